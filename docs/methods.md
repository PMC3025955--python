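# Methods

This note documents the models, conventions and numerical choices behind
`coregnet`, in the order the pipeline runs.

## 1. TFBS filtering and the P-matrix

A TFBS hit table has one row per predicted site: gene, promoter, TF, core and
matrix similarity scores in [0, 1], and an orthology-conservation flag. The
high-confidence filter keeps rows with `core_sim ≥ core_min`,
`matrix_sim ≥ matrix_min` (both default 1.0, i.e. 100 % confidence matches)
and, by default, conserved promoters only. The P-matrix collapses hits at
gene granularity: multiple sites for one TF on one gene — including sites on
different promoters of that gene — become a single 1. Genes with no surviving
site are absent from the matrix rather than present as zero rows, so every
row has at least one 1.

`PᵀP` is computed as an exact integer product. The per-gene TFBS histogram
reports the empirical central 95 % interval of row sums (2.5th/97.5th
percentiles); the shared-site distribution over all C(G, 2) unordered pairs
is tallied blockwise from `P·Pᵀ` so memory stays bounded at ~10⁴ genes.

**Degree-law fit.** TF out-degrees are fit by discrete maximum likelihood
under the zeta law `P(X = x) ∝ x^(−α)` for `x ≥ x_min` (default 1), with the
Hurwitz zeta normalizer and bounded scalar minimization on α ∈ (1, 12).
Log-log regression on binned counts is deliberately avoided (it is biased).
The fit refuses degenerate inputs: fewer than 10 nonzero degrees or fewer
than 3 distinct values.

**Partner saturation.** The partner-count-vs-target-count relation is fit as
`y = a(1 − e^(−bx)) (+ c)` by nonlinear least squares; the exponential-
saturation form is this package's choice of concrete model for a saturating
growth curve, recorded in the fit metadata. `R²` uses the standard
1 − SS_res/SS_tot definition, with `R² = 0` for constant y.

## 2. Correlation statistics

All correlations are Pearson, over condition means, with gene self-pairs
excluded. Rows are standardized once; zero-variance genes yield undefined
(NaN) correlations, are logged, and are excluded from every summary.
Conventions fixed package-wide:

* zero correlations count with the positive class, so the positive/negative
  split is exhaustive (the zero event has measure ~0 in practice);
* the binomial tail is **strict-greater**, `P(X > k)`, computed by
  `scipy.stats.binom.sf`. Under this convention the ratio-test p-value for
  74 of 149 TFs above 1 at p = ½ is exactly 0.5 (odd-n symmetry). The
  inclusive tail `P(X ≥ k)` is always exposed alongside for audit;
* correlation bins are width 0.1 on [−1, 1], right-closed, with −1 assigned
  to the first bin;
* the target/background ratio for a TF averages over its expressed targets
  (numerator) and all P-matrix genes except the TF itself (denominator); the
  positive/negative variants restrict both averages to pairs of that sign
  and return an explicit "undefined" record when the restriction empties the
  target set — this is what shrinks the per-variant TF counts.

The LOD of an event A among co-regulated pairs versus all pairs is
`ln[(k₁/n₁)/(k₂/n₂)]` from empirical counts; zero counts give NaN (flagged),
never ±inf. The TRM profile stratifies pairs by exact shared-TF count
(0..9, then ≥10 pooled) and reports the LOD per correlation bin, plus the
contrast between the (0.8, 1.0] and [−1.0, −0.8] extreme intervals.
Averaging LOD across sparse cells accumulates a small positive Jensen bias
even under the null, so null checks are performed per cell, not on the grand
mean.

## 3. Synthetic-data generator

The generator emulates the three study inputs at reduced scale. Defaults:
1,000 genes, 60 TFs, 26 conditions, 6 modules — the condition and module
counts of the emulated study design, with gene/TF counts scaled down ~9×
from the full-scale 9,242 × 333 analysis.

* **Incidence**: TF out-degrees are drawn from a discrete power law
  truncated at `n_genes` (default exponent 2.0, matching the scale-free
  degree behaviour of real promoter scans); targets are sampled without
  replacement. A configurable fraction of hits receives a sub-threshold
  similarity score and a configurable fraction fails the orthology flag
  (both default 10 %), so the filters are exercised. With the default
  exponent the resulting incidence is sparser than the full-scale data
  (most TFs have few targets); tests that need populated high-order
  shared-TF strata use a heavier tail (exponent 1.3–1.5) explicitly.
* **Expression**: each TF gets an i.i.d. standard-normal latent profile per
  condition (the simplest exchangeable condition model — real condition
  means are correlated across developmental time, which this does not
  emulate). Each target gene is the sum of signed TF effects × profiles
  plus Gaussian noise, on a log2-like scale around 8. Activators contribute
  +e, repressors −e, dual TFs an independent random sign per target
  (e = `effect_sd_units`, default 1 latent SD; noise SD default 1).
  TF rows equal their own latent profiles so TF–target correlations are
  computable. `dual_fraction` defaults to 0.75, the midpoint of the 70–80 %
  bipotential range that real-tissue co-expression is consistent with.
* **Modules**: uniform labels M1..Mk; optionally a chosen TF's targets are
  redirected into M1 at a given rate, giving a planted enrichment with
  known truth.

All draws flow from one seed through named `SeedSequence` substreams (CRC32
of the stream name), so outputs are bit-reproducible across processes and
adding draws to one stage cannot perturb another.

What passing tests on this generator do **not** show: probe-level microarray
noise, normalization artefacts, correlated condition designs, or realistic
promoter sequence content are all outside the generator's scope; results on
it validate the *computations*, not field performance.

## 4. Regulation-type simulator

One pass: genes are shuffled and chunked into blocks of 100 (the final block
smaller); TF roles are drawn — `floor(f·n)` dual, the remainder split as
evenly as possible across activator/repressor/strong activator/strong
repressor, remainder classes chosen by seeded draw; block trajectories start
from truncated `N(9, 9)` on [0, 18] and each time step adds the acting TF's
effect to its targets (dual: independent draw from {−6, −3, +3, +6} per
target). Updates are clamped to [0, 18] by default (the bounds are stated
for initialization; clamping at every step is exposed as a flag because it
affects tail behaviour). A "groups of five" variant is available behind
`group_size`; one-at-a-time is the default, as grouping was reported to make
no difference.

Pairwise trajectory correlations are pooled **within blocks**, stratified by
shared-TF count. Per-iteration summaries are also retained; pooling across
iterations is the default reading since the alternative is not specified.

**Dual-fraction estimation.** The observed curve (mean pooled correlation at
shared-TF thresholds 0..10) is compared with simulated curves on the grid
0, 0.1, ..., 1.0 by a precision-weighted L2 distance (weights
`sqrt(min(n_obs, n_sim))` pairs per support point), so sparsely populated
high-share bins do not drown the well-estimated ones. Multi-pass runs
(`n_repeats`) use a **balanced role design**: each repeat keeps exactly
`floor(f·n)` duals while each TF is dual in as close to `f·n_repeats`
repeats as possible (cyclic windows over one random permutation). This
removes the dominant variance source — whether the highest-degree hub draws
a mono role in a given pass — without changing any single pass's marginal
design. Problem sizes used in the shipped experiments: a 1,000-gene /
60-TF synthetic incidence, 20 seeds for the null/mono contrasts, 30
reference and 15 observed repeats for recovery; at these sizes recovery of
a 0.7 dual fraction lands within one grid step in ≥ 9 of 10 seeds.

## 5. Module enrichment and assortment

The enrichment probability is the hypergeometric **upper tail**
`P(X ≥ m_j)` for `m_j` module genes among `n_j` targets drawn from `N`
(the point-mass variant is exposed for audit). A TF is module-specific when
the tail < 0.05 **and** the odds ratio `(m_j/n_j)/(m_k/N) > 1`; the second
condition guards against small tails caused by under-enrichment. No
multiple-testing correction by default (matching the single-test convention
of the analysis); Benjamini–Hochberg is available behind a flag. A TF may
qualify for several modules; a best-module view marks the smallest tail.

Assortment of a module-labelled network is tested on the unordered
module × module edge table (within-module edges on the diagonal, counted
once). Expected counts come from edge-endpoint frequencies
`p_k = (2·within_k + between_k)/2E`: `E·p_k²` on the diagonal, `2E·p_k·p_l`
off it. Degrees of freedom: cells − (K−1) fitted frequencies − 1 =
`K(K+1)/2 − K` (the Hardy–Weinberg-type goodness-of-fit count). Under label
permutation on a random graph the resulting p-values are uniform
(KS-checked in the tests).

## 6. TF network

Column similarity is Pearson on the binary columns — identically the phi
coefficient of the 2×2 co-occurrence table. Constant columns are undefined
(NaN) and never form edges. PCIT pruning follows the published algorithm the
pipeline invokes by name: for every triad, first-order partial correlations
`r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²))`, triad tolerance
ε = mean of the three |partial/direct| ratios, and edge (x, y) rejected if
some z gives `|r_xy| ≤ |ε·r_xz|` and `|r_xy| ≤ |ε·r_yz|`. Numerical guards:
|r| is clipped to 1 − 1e−12 before the division, and a z whose direct
correlation to x or y is below 1e−12 is skipped (it carries no information
about the edge and would blow up the ratio). The implementation is verified
edge-for-edge against an independent brute-force triple loop in the tests.
Hubs are the top-n degrees with lexicographic tie-break (tie flagged);
the high-confidence subnetwork keeps edges with |r| strictly above 0.9 and
shared targets strictly above 100 by default.

## 7. Pipeline

Stages run in analysis order; the gene universes of the expression matrix
and P-matrix are reconciled by intersection with the dropped counts logged.
Each stage's tables are written as TSV (GraphML for the network) next to a
machine-readable `report.json`; any stage failure aborts the run with the
stage named. A single top-level seed feeds per-stage substreams.

## Known limitations

* The generator's normal latent profiles are a modeling convenience; the
  marginal law of real normalized expression is not claimed or emulated.
* With the default degree exponent the synthetic incidence is much sparser
  than the full-scale promoterome, so absolute values of shared-site
  statistics (mean shared sites, fraction ≥ 2) are far below the full-scale
  figures; only their computations, not their magnitudes, transfer.
* The naive-expectation overlay for the shared-sites-vs-correlation curve is
  not implemented (its construction is unspecified); only the observed curve
  is emitted.
* Full-scale quantities that depend on the proprietary promoter database and
  the real expression arrays are out of reach by construction and are not
  reproduced anywhere in this package.
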