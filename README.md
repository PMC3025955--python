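# coregnet

Tools for linking **promoter sharing (co-regulation) to co-expression** in a
genome-wide "promoterome" analysis, together with a regulation-type simulator,
hypergeometric module enrichment and a PCIT-pruned transcription-factor (TF)
co-occurrence network.

## Who this is for

Regulatory genomicists who have (1) a table of predicted TF binding sites
(TFBS) in gene promoters, (2) a normalized genes × conditions expression
matrix, and (3) lists of functionally coherent gene modules, and who want to
quantify — with exact combinatorial tests rather than eyeballing — how much
promoter sharing predicts co-expression, which TFs are module-specific, and
how TFs partner with each other through shared targets. A seeded synthetic
generator emulates all three inputs at configurable scale, so the entire
pipeline is testable without any proprietary download.

## The statistics at the core

* **P-matrix**: binary incidence `P[i, j] = 1` iff gene *i*'s promoter carries
  a predicted site for TF *j*; the cross-product `PᵀP` counts shared targets
  (diagonal `n_j` = per-TF target counts).
* **Target/background ratio**: for each TF, the mean correlation with its
  predicted targets divided by the mean over all genes; the number of TFs with
  ratio > 1 is tested with the exact binomial upper tail `P(X > k)` at
  `p = ½`.
* **LOD / TRM profile**: for gene pairs sharing exactly *n* TFs (motif class
  TRMₙ), the log-odds `LOD = ln[P(coexpression | co-regulation) /
  P(coexpression)]` per correlation bin.
* **Regulation-type simulation**: targets start at truncated `N(9, 9)` on
  `[0, 18]`; TFs act one per time step with effects `{−6, −3, +3, +6}`
  (1 or 2 SD), as activator, repressor, strong variants, or "dual"
  (independent signed effect per target). Sweeping the dual fraction
  0–100 % maps regulation type to the co-expression signal and lets an
  observed curve be matched to estimate the dual fraction.
* **Module enrichment**: hypergeometric upper tail `H(j, k) = P(X ≥ m_j)`
  with odds ratio `(m_j/n_j)/(m_k/N) > 1` as an under-enrichment guard;
  network assortment by a chi-square test on the module × module
  edge-endpoint table.
* **TF network**: Pearson/phi similarity of P-matrix columns pruned by the
  PCIT triad rule (an edge dies when some third TF explains it beyond a
  triad-local tolerance), then hubs, high-correlation subnetworks and path
  queries.

## Worked example

```python
from coregnet import GeneratorConfig, RunConfig, run_pipeline

report = run_pipeline(RunConfig(
    out_dir="demo_run", seed=11,
    generator=GeneratorConfig(n_genes=400, n_tfs=30, tf_degree_exponent=1.4,
                              dual_fraction=0.0, noise_sd=0.6, seed=11),
    run_trm=True))
print(report["pmatrix"]["n_genes"], report["pmatrix"]["n_tfs"])
print(report["coexpression"]["positive_fraction"])
print(report["coexpression"]["mu_abs"])
print(report["network"]["n_edges"])
```

prints

```
272 30
66.6607995423643
0.26633252255224826
35
```

meaning: of 400 simulated genes, 272 kept at least one high-confidence TFBS
(core/matrix similarity = 1, orthology-conserved) and enter the P-matrix with
30 TFs; 66.7 % of the 45,451 pairwise correlations are positive (all TFs are
mono activators/repressors here, so co-regulation leaves a positive
signature); the average absolute correlation μ is 0.266; and PCIT keeps 35 of
the 435 possible TF–TF co-occurrence edges. The run directory also holds
every stage's tables (`pmatrix.tsv`, `tf_target_ratios_*.tsv`,
`trm_lod_profile.tsv`, `tf_network_edges.tsv`, `tf_network.graphml`) and the
machine-readable `report.json`. In `report.json` the target/background ratio
test shows all 30 TFs with ratio > 1 (exact binomial `P(X > 30 | n=30) = 0`,
inclusive tail `9.3e-10`) — with zero dual TFs and low noise, every TF is
more correlated with its own targets than with the background, as it should
be.

The same stages run from the shell:

```bash
coregnet generate --seed 11 --out demo_run
coregnet all --seed 11 --out demo_run2
coregnet network --hits demo_run/tfbs_hits.tsv --expression demo_run/expression.tsv --out net_run
```

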