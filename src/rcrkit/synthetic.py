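"""Synthetic knowledge graphs and replicate expression data with planted truth.

The generator emulates the structure of a vehicle-vs-treatment bead-array
experiment: lognormal baseline intensities on a scale where an intensity floor
of 150 removes a meaningful low tail, five replicates per group, a minority of
genes measured by two probes, and signed log2 fold-change effects propagated
from a set of planted "active" upstream mechanisms through the knowledge
graph's signed edges.  Because the active mechanisms and their directions are
known, the full pipeline (normalize → test → call → score) can be checked for
recovery, calibration and specificity without any external data.

All randomness flows from ``SimulationConfig.seed`` through a fixed
stream-splitting scheme: stage s uses ``numpy.random.SeedSequence(seed,
spawn_key=(s,))`` with stage 0 = graph topology, 1 = planted truth,
2 = expression matrix.  Rerunning any stage with the same config reproduces it
exactly, independent of the other stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .knowledge_graph import (
    CausalEdge,
    Direction,
    KnowledgeGraph,
    UniverseSpec,
)
from .state_change import ExpressionExperiment, StateChange, StateChangeSet

_STAGE_GRAPH, _STAGE_TRUTH, _STAGE_EXPERIMENT = 0, 1, 2


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated study.

    Defaults describe the reference scenario used throughout the test suite:
    a 500-mechanism knowledge graph over 10,000 genes with ~20 signed targets
    per mechanism, 30 planted active mechanisms inducing |log2FC| = 1 on their
    targets, replicate noise sd 0.25 (log2), and 5 replicates per group.

    ``targets_per_mechanism`` is (mean, dispersion) of a gamma-Poisson count
    (dispersion 0 → Poisson), truncated to [1, n_genes].  ``sign_split`` gives
    probabilities of edge signs (+1, -1, 0).  ``active_directions`` may fix the
    planted directions; None draws them fair-coin.  Baseline log2 intensities
    are Normal(baseline_log2_mean, baseline_log2_sd), i.e. intensities are
    lognormal around 2**9 = 512 so the >150 intensity filter bites.
    """

    n_mechanisms: int = 500
    n_genes: int = 10_000
    targets_per_mechanism: tuple[float, float] = (20.0, 0.1)
    sign_split: tuple[float, float, float] = (0.45, 0.45, 0.10)
    n_active: int = 30
    active_directions: tuple[Direction, ...] | None = None
    effect_log2fc: float = 1.0
    noise_sd_log2: float = 0.25
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 1.5
    n_replicates: int = 5
    multiprobe_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mechanisms < 1 or self.n_genes < 1:
            raise ValueError("n_mechanisms and n_genes must be positive")
        mean_targets, dispersion = self.targets_per_mechanism
        if mean_targets < 1 or dispersion < 0:
            raise ValueError("targets_per_mechanism mean must be >=1, dispersion >=0")
        if mean_targets > self.n_genes:
            raise ValueError(
                f"mean targets {mean_targets} exceeds n_genes {self.n_genes}: "
                "cannot supply distinct targets"
            )
        if any(p < 0 for p in self.sign_split) or abs(sum(self.sign_split) - 1.0) > 1e-9:
            raise ValueError("sign_split must be nonnegative and sum to 1")
        if not 0 <= self.n_active <= self.n_mechanisms:
            raise ValueError("n_active must lie in [0, n_mechanisms]")
        if self.active_directions is not None:
            if len(self.active_directions) != self.n_active:
                raise ValueError("active_directions length must equal n_active")
            if any(d not in ("up", "down") for d in self.active_directions):
                raise ValueError("active_directions entries must be 'up' or 'down'")
        if self.effect_log2fc < 0 or self.noise_sd_log2 < 0 or self.baseline_log2_sd < 0:
            raise ValueError("effect, noise sd and baseline sd must be nonnegative")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >=2 (variance must be estimable)")
        if not 0.0 <= self.multiprobe_fraction <= 1.0:
            raise ValueError("multiprobe_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedTruth:
    """The planted active mechanisms and the gene directions they imply.

    ``expected_changes`` maps each targeted gene to the direction the planted
    activity predicts: "up" iff the net signed effect is positive, "down" iff
    negative, "either" when only ambiguous (sign-0) edges touch it or definite
    contributions cancel.
    """

    active: tuple[tuple[str, Direction], ...]
    expected_changes: dict[str, str]

    @property
    def active_mechanisms(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.active)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _mechanism_ids(n: int) -> list[str]:
    return [f"H:M{i:04d}" for i in range(n)]


def generate_knowledge_graph(config: SimulationConfig) -> KnowledgeGraph:
    """Sample a signed bipartite mechanism→gene graph per the config.

    Each mechanism draws a target count from the gamma-Poisson
    ``targets_per_mechanism`` law (min 1, max n_genes), distinct target genes
    uniformly, and edge signs from ``sign_split``.  Deterministic per seed.
    """
    rng = _stage_rng(config.seed, _STAGE_GRAPH)
    genes = _gene_ids(config.n_genes)
    mean_targets, dispersion = config.targets_per_mechanism
    edges: list[CausalEdge] = []
    signs = np.array([1, -1, 0])
    for mech in _mechanism_ids(config.n_mechanisms):
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=mean_targets * dispersion)
        else:
            lam = mean_targets
        count = int(np.clip(rng.poisson(lam), 1, config.n_genes))
        target_idx = rng.choice(config.n_genes, size=count, replace=False)
        edge_signs = rng.choice(signs, size=count, p=config.sign_split)
        edges.extend(
            CausalEdge(mech, genes[i], int(s)) for i, s in zip(target_idx, edge_signs)
        )
    return KnowledgeGraph(edges, extra_mechanisms=_mechanism_ids(config.n_mechanisms))


def plant_truth(kg: KnowledgeGraph, config: SimulationConfig) -> PlantedTruth:
    """Choose the active mechanisms and derive the gene directions they imply."""
    rng = _stage_rng(config.seed, _STAGE_TRUTH)
    mechanisms = sorted(kg.mechanisms)
    if config.n_active > len(mechanisms):
        raise ValueError("n_active exceeds the number of mechanisms in the graph")
    chosen_idx = rng.choice(len(mechanisms), size=config.n_active, replace=False)
    chosen = [mechanisms[i] for i in sorted(chosen_idx)]
    if config.active_directions is not None:
        directions = list(config.active_directions)
    else:
        directions = ["up" if u < 0.5 else "down" for u in rng.random(config.n_active)]
    active = tuple(zip(chosen, directions))
    net: dict[str, int] = {}
    touched_ambiguous: set[str] = set()
    for mech, direction in active:
        dir_sign = 1 if direction == "up" else -1
        for gene, sign in kg.downstream_targets(mech).items():
            if sign == 0:
                touched_ambiguous.add(gene)
                net.setdefault(gene, 0)
            else:
                net[gene] = net.get(gene, 0) + sign * dir_sign
    expected = {
        g: ("up" if v > 0 else "down" if v < 0 else "either") for g, v in net.items()
    }
    return PlantedTruth(active=active, expected_changes=expected)


def simulate_experiment(
    kg: KnowledgeGraph,
    truth: PlantedTruth,
    config: SimulationConfig,
) -> ExpressionExperiment:
    """Simulate linear-scale intensities for a vehicle vs treatment contrast.

    Per-gene log2 shifts in the treatment group are the sum, over planted
    active mechanisms targeting the gene, of ``±effect_log2fc`` with sign =
    edge sign × activity direction (sign-0 edges draw a random direction).
    Effects of multiple active mechanisms add on the log2 scale.  A
    ``multiprobe_fraction`` of genes is measured by two probes sharing the
    gene-level shift but with independent baselines.
    """
    if not truth.active_mechanisms <= kg.mechanisms:
        raise ValueError("planted truth refers to mechanisms absent from the graph")
    rng = _stage_rng(config.seed, _STAGE_EXPERIMENT)
    genes = sorted(set(_gene_ids(config.n_genes)) | kg.genes)
    shift = dict.fromkeys(genes, 0.0)
    for mech, direction in truth.active:
        dir_sign = 1.0 if direction == "up" else -1.0
        for gene, sign in sorted(kg.downstream_targets(mech).items()):
            s_eff = float(sign) if sign != 0 else float(rng.choice((-1.0, 1.0)))
            shift[gene] += config.effect_log2fc * s_eff * dir_sign
    n_multi = int(round(config.multiprobe_fraction * len(genes)))
    multi_idx = set(rng.choice(len(genes), size=n_multi, replace=False).tolist())
    probes: list[str] = []
    probe_map: dict[str, str] = {}
    probe_shift: list[float] = []
    for i, gene in enumerate(genes):
        n_probes = 2 if i in multi_idx else 1
        for j in range(1, n_probes + 1):
            probe = f"{gene}_p{j}"
            probes.append(probe)
            probe_map[probe] = gene
            probe_shift.append(shift[gene])
    n_probes_total = len(probes)
    k = config.n_replicates
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_probes_total)
    noise = rng.normal(0.0, config.noise_sd_log2, size=(n_probes_total, 2 * k))
    log2 = baseline[:, None] + noise
    log2[:, k:] += np.asarray(probe_shift)[:, None]
    samples = [f"vehicle_{i + 1}" for i in range(k)] + [f"treatment_{i + 1}" for i in range(k)]
    groups = {s: ("vehicle" if i < k else "treatment") for i, s in enumerate(samples)}
    intensities = pd.DataFrame(np.exp2(log2), index=probes, columns=samples)
    return ExpressionExperiment(intensities=intensities, groups=groups, probe_map=probe_map)


def generate_random_state_changes(
    universe: UniverseSpec, n: int, seed: int
) -> StateChangeSet:
    """Draw n genes uniformly without replacement with fair-coin directions.

    The synthetic log2_fold_change (±1) and p_adj (0) fields are placeholders —
    scoring consumes only gene identity and direction.
    """
    if not 0 <= n <= universe.N:
        raise ValueError(f"n={n} must lie in [0, N={universe.N}]")
    rng = np.random.default_rng(seed)
    genes = sorted(universe.universe_genes)
    idx = rng.choice(universe.N, size=n, replace=False)
    ups = rng.random(n) < 0.5
    changes = {}
    for i, up in zip(idx, ups):
        gene = genes[i]
        direction: Direction = "up" if up else "down"
        changes[gene] = StateChange(gene, direction, 1.0 if up else -1.0, 0.0)
    return StateChangeSet(changes, contrast="random")


# ---------------------------------------------------------------------------
# file interchange


def write_experiment(exp: ExpressionExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write expression.tsv (probes × samples), samples.tsv and probes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "probes": outdir / "probes.tsv",
    }
    exp.intensities.to_csv(paths["expression"], sep="\t", index_label="probe", float_format="%.6g")
    with paths["samples"].open("w", encoding="utf-8") as fh:
        fh.write("sample\tgroup\n")
        for sample in exp.intensities.columns:
            fh.write(f"{sample}\t{exp.groups[sample]}\n")
    with paths["probes"].open("w", encoding="utf-8") as fh:
        fh.write("probe\tgene\n")
        for probe in exp.intensities.index:
            fh.write(f"{probe}\t{exp.probe_map[probe]}\n")
    return paths


def read_experiment(
    expression: str | Path, samples: str | Path, probes: str | Path
) -> ExpressionExperiment:
    intensities = pd.read_csv(expression, sep="\t", index_col="probe")
    sample_sheet = pd.read_csv(samples, sep="\t")
    probe_sheet = pd.read_csv(probes, sep="\t")
    groups = dict(zip(sample_sheet["sample"].astype(str), sample_sheet["group"].astype(str)))
    probe_map = dict(zip(probe_sheet["probe"].astype(str), probe_sheet["gene"].astype(str)))
    return ExpressionExperiment(intensities=intensities, groups=groups, probe_map=probe_map)


def write_truth(truth: PlantedTruth, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "active": outdir / "truth_active.tsv",
        "expected": outdir / "truth_expected_changes.tsv",
    }
    with paths["active"].open("w", encoding="utf-8") as fh:
        fh.write("mechanism\tdirection\n")
        for mech, direction in truth.active:
            fh.write(f"{mech}\t{direction}\n")
    with paths["expected"].open("w", encoding="utf-8") as fh:
        fh.write("gene\texpected_direction\n")
        for gene in sorted(truth.expected_changes):
            fh.write(f"{gene}\t{truth.expected_changes[gene]}\n")
    return paths
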