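import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rcrkit as rk


def enum_richness(k, m, n, N):
    """Exhaustive oracle: fraction of n-subsets of [N] with >=k of the first m."""
    hits = total = 0
    for combo in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in combo if x < m) >= k:
            hits += 1
    return Fraction(hits, total)


class TestRichness:
    def test_k_zero_is_one(self):
        assert rk.richness_pvalue(0, 5, 5, 20) == 1.0

    def test_all_targets_drawn(self):
        assert rk.richness_pvalue(5, 5, 5, 20) == 1 / 15504

    def test_partial_tail_hand_enumeration(self):
        assert rk.richness_pvalue(2, 4, 5, 10) == pytest.approx(186 / 252, abs=0)

    def test_matches_enumeration_exactly_small(self):
        for N in (5, 8):
            for m in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(m, n) + 1):
                        assert rk.richness_pvalue(k, m, n, N) == float(
                            enum_richness(k, m, n, N)
                        ), (k, m, n, N)

    def test_cross_check_scipy_hypergeom(self):
        from scipy.stats import hypergeom

        rng = np.random.default_rng(5)
        for _ in range(30):
            N = int(rng.integers(20, 5000))
            m = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(0, min(m, n) + 1))
            assert rk.richness_pvalue(k, m, n, N) == pytest.approx(
                float(hypergeom.sf(k - 1, N, m, n)), rel=1e-9
            )

    def test_stable_at_large_population(self):
        p = rk.richness_pvalue(40, 200, 5000, 100_000)
        assert 0 < p < 1

    def test_nonincreasing_in_k(self):
        values = [rk.richness_pvalue(k, 10, 30, 100) for k in range(11)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("k,m,n,N", [(6, 5, 10, 20), (1, 5, 10, 8), (2, 25, 5, 20)])
    def test_bound_violations_rejected(self, k, m, n, N):
        with pytest.raises(ValueError):
            rk.richness_pvalue(k, m, n, N)


class TestConcordance:
    def test_all_success_tail(self):
        assert rk.concordance_pvalue(10, 10) == 1 / 1024

    def test_nine_of_ten(self):
        assert rk.concordance_pvalue(9, 10) == 11 / 1024

    def test_no_evaluable_evidence_is_one(self):
        assert rk.concordance_pvalue(0, 0) == 1.0

    def test_matches_exact_tail_sum(self):
        for t in range(0, 31):
            for c in range(t + 1):
                oracle = float(
                    Fraction(sum(math.comb(t, i) for i in range(c, t + 1)), 2**t)
                )
                assert rk.concordance_pvalue(c, t) == oracle, (c, t)

    def test_nonincreasing_in_c(self):
        values = [rk.concordance_pvalue(c, 12) for c in range(13)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_alternative_null_prob_uses_binomial(self):
        from scipy.stats import binom

        assert rk.concordance_pvalue(7, 10, null_prob=0.7) == pytest.approx(
            float(binom.sf(6, 10, 0.7))
        )

    def test_c_greater_than_t_rejected(self):
        with pytest.raises(ValueError):
            rk.concordance_pvalue(3, 2)


class TestScoreHypothesis:
    def test_worked_example_concordant_direction(self, toy_kg, toy_universe, all_up_changes):
        ctx = rk.make_scoring_context(toy_universe, all_up_changes)
        s = rk.score_hypothesis(toy_kg, rk.Hypothesis("H:1", "up"), all_up_changes, ctx)
        assert (s.m, s.k, s.t, s.c) == (5, 5, 5, 5)
        assert s.richness_p == 1 / 15504
        assert s.concordance_p == 1 / 32
        assert s.significant
        assert s.supporting_count == 5

    def test_worked_example_opposite_direction(self, toy_kg, toy_universe, all_up_changes):
        ctx = rk.make_scoring_context(toy_universe, all_up_changes)
        s = rk.score_hypothesis(toy_kg, rk.Hypothesis("H:1", "down"), all_up_changes, ctx)
        assert (s.c, s.t) == (0, 5)
        assert s.concordance_p == 1.0
        assert not s.significant
        assert s.supporting_count == -5

    def test_disjoint_changes_score_k_zero(self, toy_kg, toy_universe):
        sc = rk.StateChangeSet(
            {f"g{i}": rk.StateChange(f"g{i}", "up", 1.0, 0.01) for i in range(6, 11)}
        )
        ctx = rk.make_scoring_context(toy_universe, sc)
        s = rk.score_hypothesis(toy_kg, rk.Hypothesis("H:1", "up"), sc, ctx)
        assert s.k == 0
        assert s.richness_p == 1.0
        assert not s.significant

    def test_sign_zero_edges_count_in_k_not_t(self):
        kg = rk.KnowledgeGraph(
            [rk.CausalEdge("H:1", "g1", 0), rk.CausalEdge("H:1", "g2", 1)]
        )
        universe = rk.UniverseSpec(frozenset({"g1", "g2", "g3", "g4"}))
        sc = rk.StateChangeSet(
            {
                "g1": rk.StateChange("g1", "up", 1.0, 0.01),
                "g2": rk.StateChange("g2", "up", 1.0, 0.01),
            }
        )
        ctx = rk.make_scoring_context(universe, sc)
        s = rk.score_hypothesis(kg, rk.Hypothesis("H:1", "up"), sc, ctx)
        assert (s.k, s.t, s.c) == (2, 1, 1)

    def test_mechanism_outside_universe_not_an_error(self, toy_kg):
        universe = rk.UniverseSpec(frozenset({"g1", "g2", "g3", "g4", "g5"}))
        sc = rk.StateChangeSet({"g1": rk.StateChange("g1", "up", 1.0, 0.01)})
        ctx = rk.make_scoring_context(universe, sc)
        s = rk.score_hypothesis(toy_kg, rk.Hypothesis("H:2", "up"), sc, ctx)
        assert (s.m, s.k) == (0, 0)
        assert s.richness_p == 1.0

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_count_bookkeeping_invariants(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        edges = [
            rk.CausalEdge("H:1", g, int(rng.choice([1, -1, 0])))
            for g in rng.choice(genes, size=rng.integers(1, 20), replace=False)
        ]
        kg = rk.KnowledgeGraph(edges)
        universe = rk.UniverseSpec(frozenset(genes))
        n_changes = int(rng.integers(0, 31))
        changed = rng.choice(genes, size=n_changes, replace=False)
        changes = {}
        for g in changed:
            up = bool(rng.random() < 0.5)
            changes[g] = rk.StateChange(
                g, "up" if up else "down", 1.0 if up else -1.0, 0.01
            )
        sc = rk.StateChangeSet(changes)
        ctx = rk.make_scoring_context(universe, sc)
        for direction in ("up", "down"):
            s = rk.score_hypothesis(kg, rk.Hypothesis("H:1", direction), sc, ctx)
            assert 0 <= s.c <= s.t <= s.k <= min(s.m, ctx.n)
            assert 0 < s.richness_p <= 1 and 0 < s.concordance_p <= 1


class TestScoreAll:
    def test_empty_changes_yield_no_significant(self, toy_kg, toy_universe):
        sc = rk.StateChangeSet({})
        ctx = rk.make_scoring_context(toy_universe, sc)
        scored = rk.score_all(toy_kg, sc, ctx)
        assert rk.significant_hypotheses(scored) == []

    def test_worked_graph_ranks_h1_up_first(self, toy_kg, toy_universe, all_up_changes):
        ctx = rk.make_scoring_context(toy_universe, all_up_changes)
        scored = rk.score_all(toy_kg, all_up_changes, ctx)
        top = scored[0]
        assert (top.mechanism, top.direction) == ("H:1", "up")
        assert top.significant

    def test_all_ambiguous_edges_never_significant(self):
        kg = rk.KnowledgeGraph([rk.CausalEdge("H:1", f"g{i}", 0) for i in range(10)])
        universe = rk.UniverseSpec(frozenset(f"g{i}" for i in range(10)))
        sc = rk.StateChangeSet(
            {f"g{i}": rk.StateChange(f"g{i}", "up", 1.0, 0.01) for i in range(10)}
        )
        ctx = rk.make_scoring_context(universe, sc)
        scored = rk.score_all(kg, sc, ctx, keep="all")
        assert all(s.concordance_p == 1.0 and not s.significant for s in scored)

    def test_keep_best_reports_smaller_concordance_direction(
        self, toy_kg, toy_universe, all_up_changes
    ):
        ctx = rk.make_scoring_context(toy_universe, all_up_changes)
        scored = rk.score_all(toy_kg, all_up_changes, ctx)
        h1 = [s for s in scored if s.mechanism == "H:1"]
        assert len(h1) == 1 and h1[0].direction == "up"

    def test_exact_tie_keeps_both_flagged(self):
        kg = rk.KnowledgeGraph(
            [rk.CausalEdge("H:1", "g1", 1), rk.CausalEdge("H:1", "g2", -1)]
        )
        universe = rk.UniverseSpec(frozenset({"g1", "g2", "g3", "g4"}))
        sc = rk.StateChangeSet(
            {
                "g1": rk.StateChange("g1", "up", 1.0, 0.01),
                "g2": rk.StateChange("g2", "up", 1.0, 0.01),
            }
        )
        ctx = rk.make_scoring_context(universe, sc)
        scored = rk.score_all(kg, sc, ctx)
        h1 = [s for s in scored if s.mechanism == "H:1"]
        assert len(h1) == 2
        assert all(s.direction_ambiguous for s in h1)

    def test_direction_symmetry_on_sign_definite_graph(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(40)]
        edges = [
            rk.CausalEdge(f"H:{j}", g, int(rng.choice([1, -1])))
            for j in range(4)
            for g in rng.choice(genes, size=10, replace=False)
        ]
        kg = rk.KnowledgeGraph(edges)
        universe = rk.UniverseSpec(frozenset(genes))
        changed = rng.choice(genes, size=15, replace=False)
        ups = rng.random(15) < 0.5
        sc = rk.StateChangeSet(
            {
                g: rk.StateChange(g, "up" if u else "down", 1.0 if u else -1.0, 0.01)
                for g, u in zip(changed, ups)
            }
        )
        flipped = rk.StateChangeSet(
            {
                g: rk.StateChange(g, "down" if u else "up", -1.0 if u else 1.0, 0.01)
                for g, u in zip(changed, ups)
            }
        )
        ctx = rk.make_scoring_context(universe, sc)
        fctx = rk.make_scoring_context(universe, flipped)
        for j in range(4):
            for direction, mirror in (("up", "down"), ("down", "up")):
                a = rk.score_hypothesis(kg, rk.Hypothesis(f"H:{j}", direction), sc, ctx)
                b = rk.score_hypothesis(
                    kg, rk.Hypothesis(f"H:{j}", mirror), flipped, fctx
                )
                assert (a.k, a.t, a.c) == (b.k, b.t, b.c)
                assert a.richness_p == b.richness_p
                assert a.concordance_p == b.concordance_p


class TestNullRatio:
    def test_deterministic_for_fixed_seed(self, toy_kg, toy_universe, all_up_changes):
        ctx = rk.make_scoring_context(toy_universe, all_up_changes)
        r1 = rk.null_hypothesis_ratio(toy_kg, all_up_changes, ctx, n_reps=5, seed=42)
        r2 = rk.null_hypothesis_ratio(toy_kg, all_up_changes, ctx, n_reps=5, seed=42)
        assert r1 == r2

    def test_zero_structured_significance_raises(self, toy_kg, toy_universe):
        sc = rk.StateChangeSet({"g6": rk.StateChange("g6", "up", 1.0, 0.5)})
        ctx = rk.make_scoring_context(toy_universe, sc)
        with pytest.raises(ValueError, match="undefined"):
            rk.null_hypothesis_ratio(toy_kg, sc, ctx, n_reps=3, seed=1)

    def test_random_input_gives_ratio_near_one(self):
        # "structured" data that is itself random should score like the null
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(200)]
        edges = [
            rk.CausalEdge(f"H:{j}", g, int(rng.choice([1, -1])))
            for j in range(30)
            for g in rng.choice(genes, size=12, replace=False)
        ]
        kg = rk.KnowledgeGraph(edges)
        universe = rk.build_universe(kg, genes)
        ratios = []
        for seed in range(12):
            pseudo = rk.generate_random_state_changes(universe, 60, seed=seed + 500)
            ctx = rk.make_scoring_context(universe, pseudo)
            try:
                ratios.append(
                    rk.null_hypothesis_ratio(kg, pseudo, ctx, n_reps=8, seed=seed)
                )
            except ValueError:
                continue  # pseudo-structured draw had no significant hypotheses
        assert ratios, "every random draw lacked significant hypotheses"
        mean_ratio = float(np.mean(ratios))
        # symmetry: numerator and denominator follow the same law
        assert 0.2 < mean_ratio < 5.0


class TestScoredIO:
    def test_tsv_roundtrip_preserves_ranking(self, toy_kg, toy_universe, all_up_changes, tmp_path):
        ctx = rk.make_scoring_context(toy_universe, all_up_changes)
        scored = rk.score_all(toy_kg, all_up_changes, ctx)
        path = rk.write_scored_hypotheses(scored, tmp_path / "scored.tsv")
        from rcrkit.scoring import read_scored_hypotheses

        back = read_scored_hypotheses(path)
        assert [(s.mechanism, s.direction) for s in back] == [
            (s.mechanism, s.direction) for s in scored
        ]
        assert back[0].significant == scored[0].significant
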