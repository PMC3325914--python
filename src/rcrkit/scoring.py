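"""Richness and concordance scoring of upstream-mechanism hypotheses.

Given a set of directional RNA state changes and a signed causal knowledge
graph, every mechanism yields two directional hypotheses ("activity up" /
"activity down").  Each hypothesis is scored with two one-sided statistics:

* **richness** — the hypergeometric upper-tail probability that at least k of
  the mechanism's m universe targets appear among the n observed state changes
  drawn from a universe of N genes, i.e. P(X >= k) for
  X ~ Hypergeom(N, m, n).  It asks whether the hypothesis is *connected* to
  more state changes than chance allows.
* **concordance** — the binomial upper-tail probability P(X >= c) for
  X ~ Binomial(t, 1/2), where t is the number of overlapping state changes on
  sign-definite edges and c the number whose observed direction matches the
  direction the hypothesis predicts.  It asks whether the *directional*
  agreement beats a fair coin.

A hypothesis is significant when both p-values are strictly below 0.1.  No
multiplicity correction is applied across hypotheses; instead, specificity is
validated globally by re-scoring randomly generated state-change sets of the
same size, which should yield far fewer significant hypotheses than the
structured data (:func:`null_hypothesis_ratio`).

Both tail probabilities are computed with exact integer arithmetic and a
single correctly-rounded float division, so they agree bit-for-bit with
exhaustive enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .knowledge_graph import (
    DIRECTIONS,
    Direction,
    Hypothesis,
    KnowledgeGraph,
    UniverseSpec,
)
from .state_change import StateChangeSet


@dataclass(frozen=True)
class ScoringContext:
    """Universe (N) and state-change draw count (n) shared by one scoring run."""

    universe: UniverseSpec
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.n <= self.universe.N:
            raise ValueError(f"n={self.n} must satisfy 0 <= n <= N={self.universe.N}")


@dataclass(frozen=True)
class ScoredHypothesis:
    """A directional hypothesis with its overlap bookkeeping and p-values.

    ``supporting_count`` is the signed number of state changes connected to the
    hypothesis: +k for an inferred increase, -k for an inferred decrease.
    """

    hypothesis: Hypothesis
    m: int
    k: int
    t: int
    c: int
    richness_p: float
    concordance_p: float
    significant: bool
    supporting_count: int
    direction_ambiguous: bool = False
    annotation: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.c <= self.t <= self.k <= self.m:
            raise ValueError(f"counts must satisfy 0 <= c <= t <= k <= m, got {self}")

    @property
    def mechanism(self) -> str:
        return self.hypothesis.mechanism

    @property
    def direction(self) -> Direction:
        return self.hypothesis.direction


def make_scoring_context(
    universe: UniverseSpec,
    sc: StateChangeSet,
    *,
    restrict_n: bool = True,
) -> ScoringContext:
    """Build the (N, n) context for a scoring run.

    ``n`` counts the state changes whose gene lies in the universe (default) or
    all state changes (``restrict_n=False``; must still not exceed N).
    """
    if restrict_n:
        n = sum(1 for g in sc.changes if g in universe.universe_genes)
    else:
        n = len(sc.changes)
    return ScoringContext(universe=universe, n=n)


def richness_pvalue(k: int, m: int, n: int, N: int) -> float:
    """Exact hypergeometric upper tail P(X >= k), X ~ Hypergeom(N, m, n).

    Population N genes of which m are the hypothesis's targets; n genes were
    observed changed; k is the observed overlap.  Computed as an exact integer
    tail sum (term recurrence on binomial products) divided once, so the result
    is the correctly rounded double of the true rational probability for any N
    up to at least 1e5.
    """
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= m, n <= N; got m={m}, n={n}, N={N}")
    if not 0 <= k <= min(m, n):
        raise ValueError(f"need 0 <= k <= min(m, n); got k={k}, m={m}, n={n}")
    lo = max(0, m + n - N)  # lower bound of the hypergeometric support
    if k <= lo:
        return 1.0
    # term_i = C(m, i) * C(N-m, n-i); tail sum for i = k .. min(m, n)
    hi = min(m, n)
    term = math.comb(m, k) * math.comb(N - m, n - k)
    total = term
    for i in range(k, hi):
        # C(m,i+1)C(N-m,n-i-1) = C(m,i)C(N-m,n-i) * (m-i)(n-i) / ((i+1)(N-m-n+i+1))
        term = term * (m - i) * (n - i) // ((i + 1) * (N - m - n + i + 1))
        total += term
    return total / math.comb(N, n)


def concordance_pvalue(c: int, t: int, null_prob: float = 0.5) -> float:
    """Binomial upper tail P(X >= c), X ~ Binomial(t, null_prob).

    ``t`` is the number of direction-evaluable overlaps and ``c`` the number
    concordant with the hypothesis.  ``t == 0`` returns 1.0 by convention (no
    directional evidence either way).  The default null assigns up and down
    equal chance; it may be replaced, e.g. by the empirical up-fraction of the
    state-change set.  The fair-coin case is computed exactly.
    """
    if not 0 <= c <= t:
        raise ValueError(f"need 0 <= c <= t; got c={c}, t={t}")
    if not 0.0 < null_prob < 1.0:
        raise ValueError(f"null_prob must be in (0, 1), got {null_prob}")
    if t == 0:
        return 1.0
    if null_prob == 0.5:
        return sum(math.comb(t, i) for i in range(c, t + 1)) / 2**t
    return float(sps.binom.sf(c - 1, t, null_prob))


def _predicted_direction(sign: int, direction: Direction) -> Direction | None:
    """Direction a sign-definite edge predicts under the hypothesis; None if sign 0."""
    if sign == 0:
        return None
    up = (sign == 1) == (direction == "up")
    return "up" if up else "down"


def score_hypothesis(
    kg: KnowledgeGraph,
    h: Hypothesis,
    sc: StateChangeSet,
    ctx: ScoringContext,
    *,
    null_prob: float = 0.5,
    alpha_richness: float = 0.1,
    alpha_concordance: float = 0.1,
) -> ScoredHypothesis:
    """Score one directional hypothesis against a state-change set.

    Overlaps on ambiguous (sign-0) edges count toward the richness overlap k —
    the gene is causally connected to the hypothesis — but are excluded from
    the concordance trials t, since they predict no direction.  A mechanism
    with no universe targets scores k=0 and richness 1.0 (never significant).
    """
    universe = ctx.universe.universe_genes
    targets = {g: s for g, s in kg.downstream_targets(h.mechanism).items() if g in universe}
    m = len(targets)
    k = t = c = 0
    for gene, sign in targets.items():
        change = sc.changes.get(gene)
        if change is None or gene not in universe:
            continue
        k += 1
        predicted = _predicted_direction(sign, h.direction)
        if predicted is None:
            continue
        t += 1
        if change.direction == predicted:
            c += 1
    richness = richness_pvalue(k, m, ctx.n, ctx.universe.N)
    concordance = concordance_pvalue(c, t, null_prob)
    significant = richness < alpha_richness and concordance < alpha_concordance
    return ScoredHypothesis(
        hypothesis=h,
        m=m,
        k=k,
        t=t,
        c=c,
        richness_p=richness,
        concordance_p=concordance,
        significant=significant,
        supporting_count=k if h.direction == "up" else -k,
    )


def score_all(
    kg: KnowledgeGraph,
    sc: StateChangeSet,
    ctx: ScoringContext,
    *,
    null_prob: float = 0.5,
    alpha_richness: float = 0.1,
    alpha_concordance: float = 0.1,
    keep: Literal["best", "all"] = "best",
) -> list[ScoredHypothesis]:
    """Score both directions of every mechanism and rank the results.

    With ``keep="best"`` (default reporting), each mechanism is represented by
    the direction with the smaller concordance p-value; an exact tie keeps both
    directions, flagged ``direction_ambiguous``.  ``keep="all"`` returns every
    directional hypothesis.  Results are sorted by (richness_p, concordance_p,
    mechanism, direction).
    """
    kwargs = dict(
        null_prob=null_prob,
        alpha_richness=alpha_richness,
        alpha_concordance=alpha_concordance,
    )
    results: list[ScoredHypothesis] = []
    for mechanism in sorted(kg.mechanisms):
        pair = [
            score_hypothesis(kg, Hypothesis(mechanism, d), sc, ctx, **kwargs)
            for d in DIRECTIONS
        ]
        if keep == "all":
            results.extend(pair)
        else:
            up, down = pair
            if up.concordance_p < down.concordance_p:
                results.append(up)
            elif down.concordance_p < up.concordance_p:
                results.append(down)
            else:
                results.extend(replace(s, direction_ambiguous=True) for s in pair)
    results.sort(
        key=lambda s: (s.richness_p, s.concordance_p, s.mechanism, s.direction)
    )
    return results


def significant_hypotheses(scored: list[ScoredHypothesis]) -> list[ScoredHypothesis]:
    return [s for s in scored if s.significant]


def null_hypothesis_ratio(
    kg: KnowledgeGraph,
    structured_sc: StateChangeSet,
    ctx: ScoringContext,
    n_reps: int = 25,
    seed: int = 0,
    *,
    null_prob: float = 0.5,
    alpha_richness: float = 0.1,
    alpha_concordance: float = 0.1,
    pool: UniverseSpec | None = None,
) -> float:
    """Specificity check: significant-hypothesis yield on random vs structured data.

    For each repetition, a random state-change set of the same (universe-
    restricted) size as the structured one is drawn — uniform genes, fair-coin
    directions — and scored identically.  Returns
    mean(random significant count) / structured significant count; a sound
    scoring scheme on genuinely structured data gives a small ratio.

    By default random genes are drawn from the scoring universe itself.  Pass
    ``pool`` (e.g. a :class:`UniverseSpec` over *all* measured genes) to draw
    the same number of changes as the structured set from a wider population
    instead; only the draws landing in the scoring universe then contribute to
    the hypergeometric n, which mimics a random array-wide signature.
    """
    from .synthetic import generate_random_state_changes  # local: avoids import cycle

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    kwargs = dict(
        null_prob=null_prob,
        alpha_richness=alpha_richness,
        alpha_concordance=alpha_concordance,
    )
    structured_count = len(significant_hypotheses(score_all(kg, structured_sc, ctx, **kwargs)))
    if structured_count == 0:
        raise ValueError(
            "structured data yields no significant hypotheses; null ratio undefined"
        )
    draw_pool = pool if pool is not None else ctx.universe
    n_draw = len(structured_sc) if pool is not None else ctx.n
    n_draw = min(n_draw, draw_pool.N)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    counts = []
    for rep_seed in child_seeds:
        random_sc = generate_random_state_changes(draw_pool, n_draw, int(rep_seed))
        rand_ctx = make_scoring_context(ctx.universe, random_sc)
        scored = score_all(kg, random_sc, rand_ctx, **kwargs)
        counts.append(len(significant_hypotheses(scored)))
    return float(np.mean(counts)) / structured_count


def scored_to_frame(scored: list[ScoredHypothesis]) -> pd.DataFrame:
    """Tabulate scored hypotheses (one row each, ranked order preserved)."""
    return pd.DataFrame(
        {
            "mechanism": [s.mechanism for s in scored],
            "direction": [s.direction for s in scored],
            "m": [s.m for s in scored],
            "k": [s.k for s in scored],
            "t": [s.t for s in scored],
            "c": [s.c for s in scored],
            "richness_p": [s.richness_p for s in scored],
            "concordance_p": [s.concordance_p for s in scored],
            "significant": [s.significant for s in scored],
            "supporting_count": [s.supporting_count for s in scored],
            "direction_ambiguous": [s.direction_ambiguous for s in scored],
        }
    )


def write_scored_hypotheses(
    scored: list[ScoredHypothesis], path: str | Path, *, fmt: Literal["tsv", "json"] = "tsv"
) -> Path:
    path = Path(path)
    frame = scored_to_frame(scored)
    if fmt == "tsv":
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    else:
        frame.to_json(path, orient="records", indent=2)
    return path


def read_scored_hypotheses(path: str | Path) -> list[ScoredHypothesis]:
    frame = pd.read_csv(path, sep="\t")
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            ScoredHypothesis(
                hypothesis=Hypothesis(str(row.mechanism), str(row.direction)),
                m=int(row.m),
                k=int(row.k),
                t=int(row.t),
                c=int(row.c),
                richness_p=float(row.richness_p),
                concordance_p=float(row.concordance_p),
                significant=bool(row.significant),
                supporting_count=int(row.supporting_count),
                direction_ambiguous=bool(getattr(row, "direction_ambiguous", False)),
            )
        )
    return out
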