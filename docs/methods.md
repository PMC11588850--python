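# Methods

This note documents the models, procedures, numerical choices and known
limitations behind `trn_adapt`, in the order the pipeline runs them.

## Data model

Expression is log-scale, genes x samples. The ICA model is `X = M @ A`:
`M` (genes x iModulons) holds gene weights, `A` (iModulons x samples)
activities. An iModulon's *member genes* are those whose absolute weight
exceeds mean + 2·sd of the column's absolute weights; this simple rule is
adequate for the sparse synthetic weight columns but is cruder than the
distribution-fitting thresholds used on real ICA runs, and it fails on
very short columns where a single dominant weight inflates the sd it is
compared against.

## Basal activity transformation

Each iModulon gets a direction `d ∈ {+1, −1}` answering "does a high raw
activity mean more regulation or less?". With knockout samples of the
linked regulator available, the KO anchors the no-activity end:
`d = +1` iff mean(KO raw activity) > median(reference raw activity). Ties
resolve to −1 with a warning. Without KO samples an annotated direction is
required — there is no formula for deriving orientation from a regulator's
function alone, so that judgment stays with the annotator.

The shift uses quantiles over **reference (compendium) samples only**,
never study samples, because knockout and perturbation samples would drag
the no-activity baseline toward their own extreme. Quantiles are linear
interpolation between order statistics (numpy default), fixed for
reproducibility. Per iModulon:

* `d = −1`: offset = 5th reference percentile; `A' = A − offset`; `M`
  unchanged.
* `d = +1`: offset = 95th reference percentile; `A' = offset − A`; `M`
  column negated.

Both branches satisfy `M'_k A'_k = M_k (A_k − offset_k)`, so rank-1
expression predictions are preserved up to the per-component constant.
Properties that follow and are enforced by tests: the transform is exactly
invertible given (direction, offset); at most `0.05 + 1/n_ref` of
reference samples are negative per iModulon; a second transform pass is a
no-op (after the first pass the reference 5th percentile is exactly zero).
Small negative basal activities are *not* clamped — "all activity is
positive" is approximate by construction.

Regulator activity on the growth condition is judged against a threshold
of 10% of the iModulon's maximum basal activity over the reference
compendium (configurable): activity is only meaningful relative to the
dynamic range that iModulon actually displays.

## Explained variance

`R²` of a single iModulon on a gene set compares the row-centered
expression block with the row-centered rank-1 reconstruction
`M[G,k] A[k,:]`; without centering the reconstruction, an exact `X = M A`
decomposition would be penalized by its own row means. `R²` can be
negative when the component anti-predicts.

## iModulon matching

Two decompositions are compared by Pearson correlation of `M` columns over
the shared gene universe (≥ 10 genes required), matched greedily one-to-one
by descending |r|; |r| ≥ 0.6 counts as matched. The absolute value makes
matching invariant to ICA's arbitrary component signs. Greedy matching is
not globally optimal, but at the correlation separations where matching is
meaningful (clearly block-diagonal |r|), it coincides with the optimal
assignment.

## Differential activity and DEO

Neither procedure is a calibrated noise model of ICA activities; both are
simple, fully specified tests.

* Differential activity: per iModulon, Δ = |mean₁ − mean₂|, two-sample
  permutation p (label shuffling, default 10,000 permutations, seeded,
  add-one estimator), Benjamini–Hochberg across iModulons; flagged iff
  Δ > 5 basal units AND q < 0.05.
* Differentially expressed operons (DEO): gene log2FC = difference of
  condition means (input already log2); operon log2FC = mean over member
  genes; the per-operon test pools member-gene replicate values after
  centering each gene by its grand mean across both conditions (so gene
  baselines cancel), two-sample t, BH across operons; DE iff
  |log2FC| > 1 and q < 0.05. Pooling replicates across genes treats genes
  as exchangeable within an operon — reasonable for co-transcribed genes,
  anti-conservative if one gene dominates the variance.

## TF–TF network statistics

The graph keeps only genes appearing as regulators; `u → v` iff `u`
regulates `v`; self-loops dropped; effect signs and record multiplicity
ignored (signs matter only for knockout scoring). Choices where the
conventions genuinely diverge:

* *Pair connectivity* uses **ordered** pairs over **all** regulator nodes,
  including isolated ones — consistent with the directed-graph framing and
  keeps node-removal comparisons well defined.
* *Node removal* deletes the node and its edges; the recomputed fraction
  uses the remaining node count. Both the new fraction ("drops to") and
  the relative drop ("drops by") are returned, since the two phrasings
  describe different numbers.
* *Shortest-path fraction through a node* has two modes: `pair` (default;
  share of connected ordered pairs with the node on at least one shortest
  path) and `path` (paths counted with multiplicity, Σσ_st(x)/Σσ_st). The
  path-mode numerator is a raw path count, which is deliberately *not* the
  betweenness numerator Σσ_st(x)/σ_st — the two coincide only when all
  multiplicities are 1. Both are validated against an exact
  adjacency-matrix-power enumeration oracle rather than against each
  other.
* *Subnetwork skewness*: induced subgraph on {tf} ∪ targets(tf) with all
  regulon records among those genes; degree = in + out; biased
  Fisher–Pearson g1 (population moments), with the sample-adjusted variant
  as an option. Zero degree variance is signalled, not returned as NaN.

Betweenness is Brandes' algorithm (networkx), normalized by (n−1)(n−2).

## Phenotyping-plate growth calls

Savitzky–Golay smoothing with window 51 and degree 3 — a window of 50 is
accepted and rounded up, since the classical filter needs an odd window —
with polynomial interpolation at the trace boundaries. The per-well
statistic is the maximum smoothed signal. Controls go through the same
smoothing. The test is a one-sided z-test against the negative-control
mean and sd (n−1), upper tail only (growth = higher opacity), Bonferroni
over the plate's tested wells (families are never pooled across plates),
call at adjusted p < alpha = 0.05. The pipeline is scale-equivariant:
rescaling all signals leaves calls unchanged.

**Known limitation — the z-test is anti-conservative.** The z-test treats
the control sd as known, but it is estimated from the plate's
negative-control wells (often just two). At Bonferroni-scale thresholds
(z ≈ 3.3 for 94 wells) the estimated-sd statistic is heavy-tailed —
approximately Cauchy at two controls — and the maxima being compared are
themselves extreme-value statistics with a heavier-than-normal right
tail. Measured on 1,000 simulated null plates (96 wells, 2 controls), the
family-wise false-call rate is ≈ 0.72, not 0.05, and simulation shows no
realistic control count fixes it (≈ 0.09 even with half the plate as
controls). Power is unaffected: a 10σ effect is called with probability
> 0.99. The corresponding acceptance check is intentionally left failing
as a record of this property. For calibrated calls use
`growth_calls(..., method="t")`, a prediction-interval t-test
(`(s − μ̂)/(σ̂√(1+1/n))`, n−1 df) that is exact at any control count; the
z-test remains the default because it is the field's conventional
phenotyping-plate procedure and the one this pipeline models.

PCA of binary calls: columns (conditions) mean-centered, unscaled;
zero-variance conditions dropped with a warning; SVD; strain scores
`U·S`, condition loadings `V`, variance fractions `s²/Σs²`.

## Mutation convergence

Convergence groups records by the gene-or-region **label**, not exact
coordinate, so independent hits in the same promoter region count
together (positional grouping is available via `key="position"`). A gene
is convergent for a knockout when ≥ 2 **distinct lineages** carry ≥ 1
record; repeat hits within one lineage never count. Population records
below a 5% frequency floor are ignored (low enough to keep genuine
low-frequency sweeps, configurable). "Regulator-specific" convergence
means a convergent gene that is in the knocked-out regulator's regulon, is
itself the regulator of an iModulon overlapping the knockout's iModulon,
or is listed as a known post-transcriptional partner in the config —
regulon tables cannot represent e.g. sRNA-mediated partners, hence the
explicit list. The isolate/population Jaccard index is keyed by
(position, allele) by default (gene-level optional) and a both-empty
comparison is signalled rather than defined as 1.

## Classification

```
iv  if evolved growth rate < 95% of wildtype (recovery threshold, configurable)
i   if wildtype basal activity of the linked iModulon < activity threshold
iii if a regulator-specific convergent mutation exists
ii  otherwise
```

Growth recovery is operationalized as the evolved endpoint rate reaching
95% of wildtype; the underlying data reports rates, not a recovered flag,
and 95% separates "plateaued at wildtype" from partial recovery.

## Synthetic studies

The generator produces all six inputs from one seed, each generator on its
own spawned stream so artifacts can be regenerated independently; a fixed
seed gives byte-identical files.

* **TRN**: Bernoulli edges per (TF, target gene) and ordered (TF, TF)
  pair; a reserved 10% of target genes get exactly one regulator (so
  sole-regulator statistics are exercised); designated hub TFs are topped
  up to ≥ 5× the median out-degree; effects drawn
  activation/repression/dual at 0.65/0.30/0.05.
* **Expression**: each iModulon's weights (uniform 1–2) sit on one
  regulator's regulon. A latent basal activity b ≥ 0 is drawn per
  (iModulon, sample): exponential with mean `activity_scale` (default 5)
  for reference samples — most compendium samples show little activity of
  any one iModulon, and the near-zero 5th percentile is exactly the
  anchor the transform estimates. The raw activity row is `c + b`
  (direction −1) or `c − b` (+1) with a random baseline c, hiding the
  direction. Knockout samples have b = 0 — pinned at the no-activity
  extreme; wildtype samples carry each knockout's configured `effect_size`
  on its linked iModulon (0 models a regulator inactive on the
  condition). `X = M @ A` plus additive Gaussian noise (sd 0.25 default);
  the noise model is a simplification — real log-expression noise is
  heteroskedastic, and real ICA residuals are structured.
* **Plates**: growth wells are logistic, `baseline + K/(1+e^{−r(t−t0)})`,
  K = growth effect (default 50 opacity units), per-well random rate and
  lag, over 48 h at 30-min reads; non-growth and control wells are flat
  baseline; Gaussian noise sd 1.
* **Mutations**: planted convergent genes hit ≥ 2 lineages (binomial with
  a per-knockout convergence rate, floored at 2); background mutations are
  Poisson(3) per lineage drawn from lineage-disjoint gene slices, so the
  planted sets are the exhaustive convergence ground truth; endpoint
  isolates (frequency 1) pair with population samples carrying ~80% of
  the same mutations at frequencies in (0, 1].
* **Growth impacts**: 20% of genes high-impact (defect uniform 0.5–1),
  the rest uniform 0–0.3. **Growth rates**: recovered knockouts end at
  96–105% of wildtype, non-recovering at 40–80%.

What passing on these studies does **not** show: robustness to real ICA
noise structure, batch effects, operon-level correlation in expression,
plate-reader drift or edge effects, or variant-calling artifacts — the
generators emulate the statistical shape the analysis assumes, not the
instruments.

## Problem sizes used by the validation suite

Graph oracle: 200 random digraphs, ≤ 10 nodes, edge probability 0.3,
agreement to 1e-12 against exact integer adjacency-power enumeration.
Basal transform: 50 iModulons, 100 reference samples; direction recovery
under activity noise sd 1 (knockout displacement ln2·5 ≈ 3.5, i.e. ≥ 3×
the noise sd); anchoring and invertibility on the noise-free variant.
Growth calls: 1,000 null plates and 200 power plates of 94 tested wells.
Matching: 10 iModulons over a 60-gene universe, weight noise sd 0.1 on
unit-normalized columns, 20 seeds — at this universe size the expected
|r| ≈ 0.78 sits > 4σ above the 0.6 matched threshold, which is what makes
a 100%-recovery requirement meaningful (at several hundred genes the same
noise pushes |r| below 0.6 for correctly paired components).
Classification: 20 archetype studies end to end. PCA: 20 binary call
matrices, 20 strains × 96 conditions, 40% nitrogen conditions, 2% call
flips.

## Determinism

`run_study` is a pure function of (inputs, config): all randomness flows
from the config seed through named per-generator streams, and a rerun
writes a byte-identical report (paths inside the report are relative to
the output directory for exactly this reason). No caching layer exists —
recomputation is cheap and a cache could only ever return what
recomputation returns.
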