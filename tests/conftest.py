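import numpy as np
import pytest

import rcrkit as rk


@pytest.fixture
def toy_kg() -> rk.KnowledgeGraph:
    """H:1 upregulates g1..g5; H:2 carries mixed-sign edges to g6..g20."""
    edges = [rk.CausalEdge("H:1", f"g{i}", 1) for i in range(1, 6)]
    edges += [
        rk.CausalEdge("H:2", f"g{i}", 1 if i % 3 == 0 else (-1 if i % 3 == 1 else 0))
        for i in range(6, 21)
    ]
    return rk.KnowledgeGraph(edges)


@pytest.fixture
def toy_universe(toy_kg) -> rk.UniverseSpec:
    """All 20 graph targets measured: N = 20."""
    return rk.build_universe(toy_kg, {f"g{i}" for i in range(1, 21)})


@pytest.fixture
def all_up_changes() -> rk.StateChangeSet:
    """g1..g5 all called 'up' — the fully concordant case for H:1-up."""
    return rk.StateChangeSet(
        {f"g{i}": rk.StateChange(f"g{i}", "up", 1.0, 0.01) for i in range(1, 6)}
    )


@pytest.fixture(scope="session")
def reference_scenario() -> rk.ScenarioResult:
    """One full planted run at the package's default study conditions.

    Session-scoped: the simulation and scoring are deterministic for the fixed
    seed, so every test reads the same object.
    """
    return rk.run_planted_scenario(rk.SimulationConfig(seed=101))


def make_small_config(seed: int, **overrides) -> rk.SimulationConfig:
    """A scaled-down scenario for fast end-to-end tests."""
    fields = dict(
        n_mechanisms=40,
        n_genes=600,
        targets_per_mechanism=(8.0, 0.1),
        n_active=6,
        effect_log2fc=1.0,
        noise_sd_log2=0.25,
        n_replicates=5,
        multiprobe_fraction=0.3,
        seed=seed,
    )
    fields.update(overrides)
    return rk.SimulationConfig(**fields)


@pytest.fixture
def small_config() -> rk.SimulationConfig:
    return make_small_config(seed=7)


def naive_bh(p: np.ndarray) -> np.ndarray:
    """Independent step-up oracle: adj_i = min over j>=rank(i) of p_(j)*m/j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
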