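"""End-to-end composition: simulate → normalize → test → call → score.

Glue used by the CLI, the test suite and the reproduction script.  Nothing
here adds statistics; it only wires the stage modules together.
"""

from __future__ import annotations

from dataclasses import dataclass

from .knowledge_graph import KnowledgeGraph, UniverseSpec, build_universe
from .scoring import (
    ScoredHypothesis,
    ScoringContext,
    make_scoring_context,
    score_all,
    significant_hypotheses,
)
from .state_change import (
    ExpressionExperiment,
    StateChangeSet,
    call_state_changes,
    probe_statistics,
    quantile_normalize,
)
from .synthetic import (
    PlantedTruth,
    SimulationConfig,
    generate_knowledge_graph,
    plant_truth,
    simulate_experiment,
)


def call_from_experiment(
    exp: ExpressionExperiment,
    treatment: str = "treatment",
    control: str = "vehicle",
    *,
    alpha: float = 0.05,
    min_intensity: float = 150.0,
    min_fold: float = 1.3,
    normalize: bool = True,
) -> StateChangeSet:
    """Quantile-normalize (optionally), test, adjust and call state changes."""
    if normalize:
        exp = ExpressionExperiment(
            intensities=quantile_normalize(exp.intensities),
            groups=dict(exp.groups),
            probe_map=dict(exp.probe_map),
        )
    stats = probe_statistics(exp, treatment, control)
    return call_state_changes(
        stats,
        alpha=alpha,
        min_intensity=min_intensity,
        min_fold=min_fold,
        contrast=f"{treatment}_vs_{control}",
    )


@dataclass(frozen=True)
class ScenarioResult:
    """Everything produced by one planted-truth simulation run."""

    config: SimulationConfig
    kg: KnowledgeGraph
    truth: PlantedTruth
    experiment: ExpressionExperiment
    state_changes: StateChangeSet
    universe: UniverseSpec
    ctx: ScoringContext
    scored: list[ScoredHypothesis]

    @property
    def significant(self) -> list[ScoredHypothesis]:
        return significant_hypotheses(self.scored)


def run_planted_scenario(
    config: SimulationConfig,
    *,
    alpha: float = 0.05,
    min_intensity: float = 150.0,
    min_fold: float = 1.3,
    null_prob: float = 0.5,
    alpha_richness: float = 0.1,
    alpha_concordance: float = 0.1,
) -> ScenarioResult:
    """Simulate a planted study and run the full calling + scoring pipeline."""
    kg = generate_knowledge_graph(config)
    truth = plant_truth(kg, config)
    experiment = simulate_experiment(kg, truth, config)
    state_changes = call_from_experiment(
        experiment, alpha=alpha, min_intensity=min_intensity, min_fold=min_fold
    )
    universe = build_universe(kg, experiment.measured_genes)
    ctx = make_scoring_context(universe, state_changes)
    scored = score_all(
        kg,
        state_changes,
        ctx,
        null_prob=null_prob,
        alpha_richness=alpha_richness,
        alpha_concordance=alpha_concordance,
    )
    return ScenarioResult(
        config=config,
        kg=kg,
        truth=truth,
        experiment=experiment,
        state_changes=state_changes,
        universe=universe,
        ctx=ctx,
        scored=scored,
    )


def recovery_metrics(truth: PlantedTruth, scored: list[ScoredHypothesis]) -> tuple[float, float]:
    """Precision and recall of significant (mechanism, direction) pairs vs planted.

    Precision is 1.0 by convention when nothing is significant.
    """
    planted = set(truth.active)
    found = {(s.mechanism, s.direction) for s in scored if s.significant}
    if not found:
        return 1.0, 0.0
    tp = len(found & planted)
    return tp / len(found), tp / len(planted) if planted else 1.0
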