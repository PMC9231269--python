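# metabomr

Two-sample univariable and multivariable Mendelian randomisation (MR) for
prioritising candidate metabolic exposures from GWAS summary statistics.

## The problem

High-throughput NMR metabolomics panels quantify hundreds of circulating
traits (glucose, amino acids, ketone bodies, lipoprotein subclass lipids,
...), and GWAS consortia publish per-SNP association summaries for each of
them alongside outcome GWAS such as offspring birthweight.  Observational
associations between these traits and outcomes are heavily confounded; MR
uses genetic variants as instruments to probe causality.  But metabolomics
panels are massively redundant (ratios, composites, near-perfectly
genetically correlated subclass measures), and metabolic SNPs are
notoriously pleiotropic, so a credible analysis needs a disciplined
pipeline, not a single estimator.

`metabomr` implements that pipeline end to end for analysts working with
summary-level data:

1. **Panel reduction** — drop derived ratios and composite measures; keep
   one total-lipids measure per lipoprotein subclass; estimate pairwise
   genetic correlation over the instrument union and remove one member of
   every pair with rg² > 0.985.
2. **Instrument selection and harmonisation** — greedy LD clumping at
   p < 5×10⁻⁸ and r² < 0.01 against a supplied LD matrix; alignment of
   outcome effects to the exposure's effect allele, with palindromic SNPs
   resolved by allele frequency and removed when MAF > 42%.
3. **Univariable MR (UVMR)** — Wald ratio (K = 1) or inverse-variance
   weighted (IVW) estimate (K ≥ 2), with Cochran's Q, mean F-statistics and
   leave-one-out diagnostics.  IVW is the weighted regression through the
   origin

   θ̂ = Σⱼ βXⱼ βYⱼ σYⱼ⁻² / Σⱼ βXⱼ² σYⱼ⁻² ,

   with a multiplicative random-effects standard error bounded below by the
   fixed-effect one.
4. **Screening and multivariable MR (MVMR)** — traits with UVMR p < 0.05
   become candidates; their instruments are pooled, cross-trait clumped, and
   the direct effects estimated jointly as θ̂ = (BₓᵀWBₓ)⁻¹BₓᵀW βY with
   W = diag(σY⁻²).  Per-exposure conditional F-statistics (weak-instrument
   diagnostics given the other exposures, using a phenotypic correlation
   matrix to approximate SNP-effect covariances) and a Q-statistic with
   L − K − 1 degrees of freedom are reported.
5. **Pleiotropy-robust sensitivity estimators** — MR-Egger (slope +
   directional-pleiotropy intercept), weighted median, and weighted mode,
   the latter two with seeded parametric-bootstrap standard errors.

A first-class synthetic-data generator (`metabomr.synthgwas`) draws
two-sample summary statistics with known causal effects, configurable
instrument strength, pleiotropy, LD blocks and sample overlap, so every
stage is testable without any data download.

## Worked example

```python
from metabomr import make_reference_panel, run_analysis

truth = make_reference_panel(seed=1)          # 12-trait synthetic panel
report = run_analysis(
    truth.traits, truth.exposures, truth.outcome, truth.ld, rho=truth.rho
)
```

The panel contains three causal traits (a glucose-like trait with true
effect 0.33 SD outcome per SD exposure, glutamine-like 0.09, alanine-like
0.14), nine null traits including a near-duplicate pair and one trait with
no significant instruments.  Printing the key results:

```text
traits kept after filtering: 11 / 12
UVMR  glucose    +0.334 (95% CI +0.302, +0.366)  p=5.06e-93  K=20
UVMR  glutamine  +0.082 (95% CI +0.047, +0.117)  p=4.44e-06  K=19
UVMR  alanine    +0.151 (95% CI +0.110, +0.192)  p=6.28e-13  K=17
UVMR  apob       -0.012 (95% CI -0.046, +0.021)  p=4.72e-01  K=20
candidates: glucose, glutamine, alanine
MVMR  glucose    +0.328 (95% CI +0.291, +0.365)  conditional F=39.0
MVMR  glutamine  +0.070 (95% CI +0.034, +0.105)  conditional F=40.2
MVMR  alanine    +0.143 (95% CI +0.101, +0.185)  conditional F=29.6
Q = 70.8 on 52 df (p = 0.04)
```

One member of the near-duplicate lipid pair was pruned (11/12 kept), the
three causal traits — and only they — pass the p < 0.05 screen, the UVMR
and MVMR estimates bracket the generating effects, a null lipid trait (apoB)
is estimated tightly around zero, and all conditional F-statistics are well
above the conventional weak-instrument threshold of 10.

The same analysis runs from the shell against TSV inputs:

```bash
metabomr simulate --seed 1 --out panel/     # write the panel as TSV files
metabomr run --config config.yaml           # full pipeline, reports as TSV
```

`run` writes `filter_report.tsv`, `uvmr_results.tsv`, `loo_results.tsv`,
`candidates.tsv`, `mvmr_results.tsv`, `sensitivity_results.tsv` (forest-
plot-ready tidy tables) and `provenance.json`; re-running a config is
byte-identical.

## Layout

```
src/metabomr/
  gwas_io.py      summary-table and trait-metadata IO + record types
  harmonise.py    allele alignment, palindrome rules, LD clumping
  trait_filter.py panel-reduction stages, genetic-correlation pruning
  uvmr.py         Wald ratio, IVW, mean F, leave-one-out, dispatch
  sensitivity.py  MR-Egger, weighted median, weighted mode
  mvmr.py         MVMR-IVW, conditional F, Q-statistic, panel assembly
  pipeline.py     orchestration, config, tidy reports
  synthgwas.py    synthetic summary-statistics generator
  cli.py          `metabomr` command-line entry point
docs/methods.md   modelling assumptions, conventions, limitations
```
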