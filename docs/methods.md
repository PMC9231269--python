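# Methods

This note records the statistical model behind `metabomr`, the conventions
and tunable parameters, what the synthetic-data generator does and does not
emulate, and the design choices made where the methodology was genuinely
open.

## Model and assumptions

Two-sample MR treats per-SNP association pairs (β̂_Xj, β̂_Yj), estimated in
separate (possibly overlapping) samples, as noisy observations of a linear
system: under the instrumental-variable assumptions (relevance, no
confounding of the SNP–outcome relation, exclusion restriction), the true
SNP–outcome effect of instrument j is θ·γ_j, where γ_j is its SNP–exposure
effect and θ the causal effect of the exposure on the outcome in SD units.
Horizontal pleiotropy adds a per-SNP intercept α_j, which the sensitivity
estimators target in different ways:

- **IVW** assumes α_j = 0 for all j; it is the efficient weighted
  regression of β̂_Y on β̂_X through the origin with weights σ_Yj⁻².
- **MR-Egger** allows a common directional component: under the InSIDE
  assumption (pleiotropy independent of instrument strength) the
  regression-with-intercept slope remains consistent and the intercept
  estimates mean pleiotropy.  Records are first oriented so β_Xj ≥ 0, which
  makes the intercept well defined; the slope is invariant to that step.
- **Weighted median** is consistent when ≥ 50% of the weight lies on valid
  instruments; **weighted mode** when the largest homogeneous cluster of
  per-SNP ratios is valid.
- **MVMR-IVW** regresses β̂_Y on the L×K matrix of exposure effects jointly,
  so pleiotropy acting *through the modelled exposures* is absorbed; its
  estimates are direct effects, conditional on the other exposures.

All exposures are assumed standardised (unit variance), so effects are SD
per SD throughout.

## Conventions and defaults

| Parameter | Default | Meaning |
|---|---|---|
| `p_instrument` | 5×10⁻⁸ | genome-wide significance for instrument selection |
| `r2_clump` | 0.01 | max pairwise LD r² among instruments |
| `maf_palindrome` | 0.42 | strict MAF limit above which palindromic SNPs are ambiguous; applied to min(eaf, 1−eaf) on *both* exposure and outcome sides |
| `p_screen` | 0.05 | UVMR p-value below which a trait enters MVMR |
| `rg2_prune` | 0.985 | squared genetic correlation above which one trait of a pair is removed |
| `boot_reps` | 1000 | parametric-bootstrap replicates for median/mode SEs |
| `phi` | 1.0 | weighted-mode bandwidth multiplier |

Fixed numerical conventions, chosen once and used everywhere:

- **Confidence intervals** are normal-quantile 95% intervals
  (± 1.959964·SE) for every estimator, including MR-Egger; no small-sample
  t correction is applied anywhere.
- **IVW / Egger / MVMR standard errors** use a multiplicative residual
  scale bounded below by 1 ("capped multiplicative"): the fixed-effect SE
  is inflated by the residual standard deviation when the data are
  overdispersed, never deflated.  A pure fixed-effect mode is exposed
  (`re_mode="fixed"`); it is the correctly specified variance model when
  there is no heterogeneity, and calibration of the IVW test at the nominal
  level is a property of that mode — the capped default is deliberately
  conservative under the null.
- **Wald ratio SE** is first-order delta method (σ_Y/|β_X|), ignoring
  β_X uncertainty; adequate for genome-wide-significant instruments.
- **Clumping** is greedy by ascending p with ties broken lexicographically
  by SNP id, making it fully deterministic.  LD comes only from the
  supplied matrix; no physical-distance window is applied, since the r²
  rule is the binding constraint when r² is given directly.
- **Weighted median** interpolates the sorted ratios linearly in the
  cumulative-midpoint weight p_j = cumsum(w)_j − w_j/2 at 0.5, with
  first-order inverse-variance weights w_j = β_Xj²/σ_Yj².
- **Weighted mode** uses the modified Silverman bandwidth
  h = φ·0.9·min(SD, 1.4826·MAD)·K^(−1/5); the min is taken over the
  positive spread measures so a degenerate MAD with genuinely spread ratios
  falls back to the SD.  The argmax is located on a 512-point grid over
  [min−3h, max+3h] and polished by golden-section search; bootstrap
  replicates use the grid argmax only.  Identical ratios (h = 0) return the
  common ratio.
- **Bootstrap SEs** are parametric (effects redrawn from normals centred on
  the observations), seeded; nonparametric resampling of SNPs is unstable
  at the K ≈ 10–50 typical here.
- **Conditional F** follows the Q-minimisation construction: for exposure
  k, Q_x,k(δ) = Σⱼ (β_jk − δᵀβ_j,−k)²/v_j(δ) with v_j built from the SNP
  SEs and the phenotypic correlation matrix (cov ≈ ρ·se·se), minimised by
  iterated WLS with the weights frozen within each step (fixed-point
  tolerance 10⁻⁸, max 100 iterations), then divided by L − K + 1.  The
  divisor is fixed by the requirement that K = 1 reduce exactly to the mean
  F-statistic.  The IWLS is a *local* solver: on pathological flat
  objectives (two mutually irrelevant exposures) the exact Q surface can
  have shallower dips at large |δ|, but in the intended regime — exposures
  with genuine partial overlap — the fixed point and the global minimum
  coincide (verified against a dense-grid minimiser).
- **Genetic correlation** between traits is the weighted Pearson
  correlation of per-SNP effect estimates over the instrument union,
  weights 1/(se·se), clipped to [−1, 1].  This is a pragmatic
  summary-statistic estimator of the instrumented genetic signal, not
  LD-score regression; a correlation matrix can be supplied from file
  instead, and the pruning rule is agnostic to its source.
- **Pair pruning** removes the trait later in a deterministic priority
  order (default: input order), iterating pairs in decreasing rg².
- When no phenotypic correlation matrix is supplied, MVMR falls back to the
  identity with a loud warning; conditional Fs then ignore exposure
  correlation.

## The synthetic-data generator

`synthgwas` draws summary statistics directly — no individual-level
genotypes — because the pipeline consumes only summary data and direct
generation gives exact control of instrument strength (per-SNP expected
F = 1 + n·2·maf·(1−maf)·γ²), pleiotropy and overlap:

- true SNP–outcome effects are γ_Y = Γθ + α, with α drawn
  Normal(mean, sd) for balanced/directional pleiotropy;
- observed effects are Normal(truth, se²) with the standard unit-variance
  GWAS standard error se = (n·2·maf·(1−maf))^(−1/2);
- within one SNP, sampling errors across exposures follow the phenotypic
  correlation matrix ρ, and exposure–outcome error correlation equals
  overlap_fraction × ρ_XY — a first-order model of shared samples, enough
  to demonstrate overlap bias, not to quantify it precisely;
- SNPs inside an LD block get marginal effects R·(joint effects) and
  error correlation R;
- a configurable fraction of SNPs is palindromic, and the outcome table
  reports a fraction of SNPs with swapped allele labels or on the
  opposite strand, so harmonisation is exercised end to end (estimates
  would be visibly wrong if a sign rule broke);
- defaults mirror a large-biobank exposure GWAS (n_x = 115,078), a
  birthweight-scale outcome meta-analysis (n_y = 210,267) and ~30%
  sample overlap.

The generator does **not** emulate: winner's curse from selecting and
estimating in the same finite sample (effects are drawn around the truth,
not re-estimated), fine-scale LD, allele-frequency-dependent genetic
architecture, population stratification, or maternal/foetal genotype
correlation (the intended outcome GWAS is consumed already adjusted).
Passing tests therefore certify the estimators and the plumbing under the
stated generative model, not robustness to those real-data complications.

`make_reference_panel` fixes one reference scenario: 12 traits across the
NMR presentation classes — three causal (0.33, 0.09, 0.14 SD/SD, the scale
of reported glucose/glutamine/alanine effects on birthweight), nine null
including a near-duplicate lipid pair (rg² > 0.985) and one trait with no
genome-wide-significant SNPs — with 20 instruments per instrumented trait
at mean F ≈ 100.  That instrument strength sits inside the mean-F range a
large biobank GWAS actually yields (roughly 55–300 across traits) and is
chosen so the p < 0.05 screen has essentially full power for the smallest
true effect; at mean F ≈ 60, weak-instrument regression dilution of order
1/F is already visible as a ~1–2% downward bias on a 0.29 effect and
depresses CI coverage toward 90% — a real property of IVW-type estimators
worth knowing when interpreting borderline conditional Fs.

## Simulation sizes

The test suite and acceptance script use replicate counts chosen to keep
Monte-Carlo error well inside the asserted bands: 100 random fixtures for
oracle equivalence, 1000 replicates for null-rejection rates (binomial SE
≈ 0.7pp at 5%), 500 for parameter recovery/coverage and pleiotropy bias,
and 60–100 seeds for panel-level candidate-recovery rates.  Single
simulations use L between 30 and 10,000 SNPs depending on the property
under test.

## Known limitations

- The genetic-correlation estimator is instrument-based; traits whose
  correlation lives mostly outside the instrument union will be
  under-pruned (supply an external matrix in that case).
- No proxy-SNP lookup: instruments missing from the outcome GWAS are
  dropped, not imputed.
- No Steiger filtering, MR-PRESSO, MVMR-Egger, or SIMEX-corrected Egger.
- MVMR assembly aligns every table to the first candidate's effect allele;
  tables from panels with inconsistent indel encodings should be
  pre-normalised.
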