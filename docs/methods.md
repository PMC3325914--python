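# Methods

## The inference problem

Given a two-group replicate expression experiment (treatment vs vehicle) and
a knowledge graph of signed causal edges *mechanism → gene expression*, the
package infers which upstream mechanisms changed activity. The reasoning is
reverse-causal: rather than asking which annotated gene sets are enriched, it
asks which *cause* nodes, if perturbed in a particular direction, would have
produced the observed pattern of directional expression changes.

## State-change calling

**Normalization.** Columns are quantile-normalized: entry i of a column is
replaced by the mean, across columns, of the values at rank i; tied entries
within a column receive the mean of the reference values over their tied rank
span. Quantile normalization assumes the bulk of the distribution is
unchanged between groups; when a large fraction of genes shifts in one
direction it will attenuate those shifts (this is visible in small simulated
panels and is a property of the method, not of this implementation). The
intensity filter is applied to the normalized matrix; `normalize=False`
switches the whole pipeline to raw intensities.

**Test statistic.** Per probe, an ordinary two-sample pooled-variance *t*
on log2 intensities with a two-sided p-value. This is a deliberate
substitution for a moderated (empirical-Bayes) linear-model fit: with five
replicates per group the moderation mainly stabilizes near-zero variances,
and the plain statistic keeps the pipeline fully specified and
dependency-light. Probes with zero pooled variance get p = 1 when the group
means are equal and p = 0 otherwise. No background correction is applied;
input is assumed raw or already background-corrected.

**Filters and probe collapse.** A probe changes iff adjusted p ≤ `alpha`
(0.05; Benjamini–Hochberg across all probes of the contrast), the larger of
the two linear-scale group means exceeds `min_intensity` (150, strict), and
the linear fold change (treatment mean / control mean) exceeds `min_fold`
(1.3) in either direction (ratio > 1.3 or < 1/1.3, strict). A gene changes
if at least one of its probes changes; its reported direction and statistics
come from the passing probe with smallest adjusted p (ties: larger |log2
fold|, then probe id). Genes whose passing probes disagree in direction are
excluded from the call set and reported in a separate ambiguous-gene table —
the inclusion rule is standard, the conflict rule is this package's choice.

**Outlier screening.** Principal-component coordinates of the samples are
written for visual inspection (`sample_pca`); no automatic exclusion is
performed because sound exclusion criteria are study-specific.

## Hypothesis scoring

Let the *universe* be the N genes both measured in the experiment and
appearing as an edge target in the graph (configurable to all measured genes
via `restrict_to_graph=False`; the restricted default keeps richness
comparable across hypotheses, since only graph-connected genes can ever
support one). Let n count state changes with genes in the universe
(`restrict_n=False` counts all).

For a hypothesis (mechanism M, direction d ∈ {up, down}) with m universe
targets:

* k = targets that are state changes (**richness overlap**);
* t = those k on sign-definite edges (**concordance trials**) — sign-0 edges
  connect the gene to the hypothesis but predict no direction, so they count
  in k and not in t;
* c = those t whose observed direction equals edge sign × d (**concordant**).

Richness p = P(X ≥ k), X ~ Hypergeom(N, m, n); concordance p = P(X ≥ c),
X ~ Binomial(t, p₀) with p₀ = ½ by default (configurable, e.g. to the
empirical up-fraction of the calls; t = 0 gives p = 1 by convention).
Significance requires both p-values strictly below 0.1. Per mechanism, the
direction with the smaller concordance p is reported; an exact tie reports
both directions flagged `direction_ambiguous`. Ranking is by
(richness p, concordance p) ascending.

**Exact tails.** Both statistics are exact: the hypergeometric tail is an
integer term-recurrence sum divided once (correctly rounded for N up to at
least 10⁵ — Python integers are unbounded, so no overflow or cancellation),
and the fair-coin binomial tail is `sum(C(t,i), i=c..t) / 2^t`. This
matters because with m ≈ 20 targets the usable tail probabilities sit near
the 0.1 threshold, where double-precision approximations could flip
significance flags.

**No multiplicity correction across hypotheses.** The dual gate is
calibrated globally instead: `null_hypothesis_ratio` re-scores random
state-change sets of the same size (genes uniform in the universe,
directions fair-coin) and reports mean(random significant count) /
(structured significant count). An option draws the random genes from a
wider pool (e.g. all measured genes) to mimic an array-wide random
signature; the default draws from the universe itself, the stricter test.

## The synthetic benchmark

`SimulationConfig` defaults define the reference conditions used throughout
the tests:

| parameter | default | rationale |
|---|---|---|
| n_mechanisms | 500 | desk-scale stand-in for a curated knowledgebase |
| n_genes | 10,000 | whole-genome-array order of magnitude |
| targets_per_mechanism | mean 20, dispersion 0.1 (gamma-Poisson, min 1) | tens of curated targets per mechanism; mild overdispersion |
| sign_split | (0.45, 0.45, 0.10) | curated causal edges carry a modest ambiguous-sign fraction |
| n_active | 30 | a strong multi-pathway perturbation |
| effect_log2fc | 1.0 (log2) | two-fold effects, comfortably above the 1.3 fold filter |
| noise_sd_log2 | 0.25 (log2) | replicate CV ~18%, typical of expression arrays |
| baseline_log2_mean / sd | 9.0 / 1.5 | lognormal intensities around 512 so the >150 floor removes a meaningful low tail |
| n_replicates | 5 | the design the caller assumes |
| multiprobe_fraction | 0.3 | a sizable minority of genes measured by two probes |

Effects of multiple active mechanisms targeting one gene add on the log2
scale; sign-0 edges transmit the effect with a random direction. All
randomness flows from one seed via `SeedSequence(seed, spawn_key=(stage,))`
(stage 0 graph, 1 truth, 2 matrix), so stages rerun reproducibly in
isolation.

**What the generator does not model:** bead-level noise, batch effects,
probe cross-hybridization, correlated genes, heavy-tailed noise, multi-hop
causal propagation (active mechanism → other mechanisms), or multiple
concentrations per treatment. The noise model is a stand-in — no noise model
accompanies real curated datasets of this design — so passing benchmarks
demonstrate internal consistency of the pipeline under idealized
assumptions, not performance on any particular real platform.

## Behavior of the specificity ratio at benchmark scale

Under the default conditions the planted mechanisms are recovered essentially
perfectly (precision and recall ≈ 1 across seeds), while the random-data
specificity ratio measures about 5–8% rather than below 5%. This is a
dimensional property, not noise: with m ≈ 20 targets, N ≈ 6,400 and n ≈ 500,
a random draw overlaps a mechanism k ≥ 4 times with probability ≈ 0.06 (the
smallest k whose richness tail clears 0.1), and the better-scoring direction
clears the concordance gate with probability ≈ 0.1, so ~500 mechanisms yield
roughly two random hits per draw against ~30 structured hits. Smaller
ratios require either a larger structured signal relative to the mechanism
count, larger target sets (finer-grained richness tails), or random
signatures drawn from a pool wider than the universe (the `pool` option).
The ratio is still a ~15-fold separation between structured and random data;
users should calibrate the expected ratio for their own graph dimensions with
`null_hypothesis_ratio` rather than assume a universal constant.

## Numerical and degenerate-input conventions

* Richness bounds are validated (0 ≤ k ≤ min(m, n), m ≤ N, n ≤ N); k at or
  below the support's lower bound max(0, m+n−N) returns exactly 1.0.
* A mechanism with no universe targets scores k = 0, richness 1.0 — valid,
  never significant.
* Duplicate knowledge-graph rows collapse; (mechanism, gene) pairs with
  conflicting signs collapse to sign 0. Mechanism and gene namespaces must be
  disjoint (mechanisms are prefixed, e.g. `H:`).
* Empty expression matrices, negative intensities, non-positive intensities
  under log2, p-values outside [0,1], and n > N random draws raise errors.
* Quantile normalization of a single column is the identity; the transform is
  idempotent on tie-free matrices.
* Percentages are rounded half-up to one decimal, matching printed-report
  style.
* Report files contain no timestamps, so reruns are byte-identical.

## Problem sizes used in the test suite

The acceptance-style checks run the reference conditions (500 mechanisms ×
10,000 genes) once per seed — about one second per run — with 10 seeds for
recovery and 25 random repetitions for specificity; oracle-equivalence
checks enumerate all hypergeometric configurations with N ≤ 12 exhaustively
and cross-check 20 larger configurations against 10⁵ Monte-Carlo draws.
These sizes were chosen so the whole suite completes in well under a minute
while leaving the statistical assertions sharp.
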