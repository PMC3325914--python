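# rcrkit

Reverse causal reasoning for transcriptomic data: infer which upstream
molecular mechanisms (transcription factors, kinases, receptors, processes)
plausibly *caused* an observed set of gene-expression changes, by scoring
directional hypotheses against a signed causal knowledge graph.

The package is aimed at computational biologists who have (a) a replicate
expression matrix for a treatment-vs-vehicle contrast and (b) a curated set of
signed causal relationships of the form *mechanism activity → gene
expression* (sign +1: activation increases expression; −1: decreases;
0: direction ambiguous). It provides the full chain:

1. **State-change calling** (`rcrkit.state_change`) — quantile normalization,
   per-probe pooled-variance *t* tests on log2 intensities,
   Benjamini–Hochberg FDR, and three filters (adjusted *p* ≤ 0.05, group mean
   intensity > 150, absolute fold change > 1.3), with multi-probe genes
   collapsed by the "at least one probe changed" rule. The result is a set of
   per-gene directional calls ("up"/"down").
2. **Hypothesis scoring** (`rcrkit.scoring`) — every mechanism yields two
   directional hypotheses (activity up / down). Each is scored with two
   one-sided statistics over the universe of N genes that are both measured
   and targeted by some edge:

   * **richness** = P(X ≥ k), X ~ Hypergeom(N, m, n): probability that at
     least k of the mechanism's m universe targets appear among the n observed
     state changes by chance;
   * **concordance** = P(X ≥ c), X ~ Binomial(t, ½): probability that at
     least c of the t sign-definite overlaps agree with the hypothesis's
     predicted directions by coin flipping.

   A hypothesis is significant when both p-values are < 0.1 (no
   per-hypothesis multiplicity correction; specificity is instead checked
   globally, see below). Both tails are computed with exact integer
   arithmetic, so they agree bit-for-bit with exhaustive enumeration.
3. **Random-data specificity** (`null_hypothesis_ratio`) — re-scores random
   state-change sets of the same size (uniform genes, fair-coin directions)
   and reports the ratio of significant-hypothesis counts, random over
   structured. Structured data should dominate.
4. **Synthetic benchmarks** (`rcrkit.synthetic`) — a generator for knowledge
   graphs and replicate bead-array-like intensity matrices with *planted*
   active mechanisms, so recovery, calibration and specificity are all
   measurable with known ground truth.
5. **Cross-treatment comparison** (`rcrkit.compare`) — exclusive Venn-region
   counts of shared state changes, printed-style percentages, and a
   significant-hypothesis table across treatment panels with
   direction-consistency flags.

## Worked example

Simulate the default benchmark — a 500-mechanism knowledge graph over 10,000
genes (~20 signed targets per mechanism), 30 planted active mechanisms with
|log2FC| = 1.0, replicate noise sd 0.25, five replicates per group — then
call state changes and score every hypothesis:

```python
import rcrkit as rk

config = rk.SimulationConfig(seed=42)
result = rk.run_planted_scenario(config)
print(f"state changes called: {len(result.state_changes)} "
      f"(universe N={result.universe.N}, n={result.ctx.n})")
precision, recall = rk.recovery_metrics(result.truth, result.scored)
print(f"significant hypotheses: {len(result.significant)} of {len(result.scored)} reported")
print(f"planted-mechanism recovery: precision={precision:.2f}, recall={recall:.2f}")
top = result.scored[0]
print(f"top hypothesis: {top.mechanism} ({top.direction}), "
      f"k={top.k}/m={top.m}, richness p={top.richness_p:.2e}, "
      f"concordance p={top.concordance_p:.2e}, support={top.supporting_count:+d}")
ratio = rk.null_hypothesis_ratio(result.kg, result.state_changes, result.ctx,
                                 n_reps=25, seed=43)
print(f"random-data specificity ratio: {100 * ratio:.1f}%")
```

prints

```
state changes called: 530 (universe N=6395, n=525)
significant hypotheses: 30 of 727 reported
planted-mechanism recovery: precision=1.00, recall=1.00
top hypothesis: H:M0087 (down), k=30/m=32, richness p=5.25e-31, concordance p=1.86e-09, support=-30
random-data specificity ratio: 6.5%
```

Reading the output: 530 genes passed the state-change filters; of these, 525
lie in the 6,395-gene scoring universe. Scoring both directions of all 500
mechanisms and keeping, per mechanism, the direction with stronger
concordance leaves 727 reported hypotheses (ties keep both directions), of
which 30 clear the dual significance gate — exactly the 30 planted
mechanisms, each with the correct direction (precision = recall = 1). The
top hypothesis explains 30 of its 32 universe targets; its negative support
count marks an inferred *decrease* in activity. On randomly generated
state-change sets of the same size, the same gate passes on average only
~6.5% as many hypotheses as on the structured data.

The same workflow is available from the shell:

```
rcrkit simulate --seed 42 --outdir sim/
rcrkit call  --expr sim/expression.tsv --samples sim/samples.tsv \
             --probes sim/probes.tsv --outdir calls/
rcrkit score --kb sim/kb.tsv --changes calls/state_changes.tsv \
             --measured genes.txt --out scored.tsv
rcrkit nullcheck --kb sim/kb.tsv --changes calls/state_changes.tsv \
                 --measured genes.txt --reps 25 --seed 1
rcrkit compare --panel low=sc_low.tsv:scored_low.tsv \
               --panel high=sc_high.tsv:scored_high.tsv --outdir report/
```

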