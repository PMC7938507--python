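# Methods

## The estimation problem

Birthweight responds to two correlated genomes: the fetus's own genotype and
the maternal genotype acting through the intrauterine environment
(maternal–fetal genotype correlation ≈ 0.5 under Mendelian transmission).
A naive two-sample MR of a maternal exposure on offspring birthweight using
ordinary outcome GWAS effects would conflate the two paths. `duomr`
therefore consumes *partitioned* outcome effects — maternal-specific
(conditional on fetal genotype) and fetal-specific (conditional on maternal
genotype) — and treats each as the outcome side of an otherwise standard
two-sample MR. The package implements the duo conditional-regression
analogue of the partition (OLS of outcome on maternal and fetal genotype
jointly); the structural-equation machinery used by biobank-scale GWAS to
obtain such effects from non-duo samples is out of scope, and its outputs
are consumed as data.

## Estimators and conventions

All estimators operate on harmonized instruments (β̂_X, σ_X, β̂_Y, σ_Y per
SNP). Conventions that are genuinely open choices, and what this package
does:

- **IVW**: weighted regression through the origin, weights 1/σ_Y². The SE is
  the fixed-effect SE inflated by √max(1, Q/(L−1)) — multiplicative
  random-effects with the residual scale floored at 1. The floor means SEs
  are never *deflated* when instruments are under-dispersed, matching the
  convention of the widely used R two-sample MR tooling whose published
  outputs this battery is designed to reproduce. Normal inference.
- **MR-Egger**: instruments are first oriented so every β̂_X ≥ 0 (β̂_Y flipped
  jointly); weighted regression with intercept, same SE floor; inference on
  slope and intercept uses t(L−2); residual Q has L−2 df. A single
  convention is hard-coded but recorded in the report metadata
  (`diagnostics.json`) so downstream readers know which was used.
- **Weighted median**: ordered Wald ratios, estimate where standardized
  cumulative weights (β̂_X/σ_Y)² cross 0.5, linearly interpolated between
  adjacent ratios. SE by parametric bootstrap: both β̂_X and β̂_Y are
  resampled from normals centred on the observed values (default 1000
  replicates, explicit seed required). Normal CI/p.
- **Mode estimators**: normal-kernel weighted density of the Wald ratios,
  bandwidth h = φ · 0.9·min(sd, MAD)/L^{1/5} with the normal-consistent MAD
  (φ default 1), evaluated on a 512-point grid spanning the ratios ± 3h;
  argmax ties break to the smallest ratio. Simple mode weights equally,
  weighted mode by inverse ratio variance. The bootstrap SE uses the
  normal-consistent MAD of the bootstrap draws rather than the standard
  deviation — the mode's bootstrap distribution is heavy-tailed and the
  robust scale is the convention for this estimator. Normal CI/p.
- **Cochran's Q**: Σ w_j(θ̂_j − θ̂_IVW)² with w_j = (β̂_Xj/σ_Yj)², df = L−1,
  upper-tail χ². Identical algebraically to the IVW weighted residual sum.
- **I²_GX**: (Q_GX − (L−1))/Q_GX with Q_GX the inverse-variance-weighted
  heterogeneity of |β̂_X| (weights 1/σ_X²), truncated below at 0. The
  statistic's weighting is not uniquely pinned down in common usage; the
  unsigned/inverse-variance choice is recorded in output metadata. Values
  below 0.9 raise a warning because MR-Egger then suffers regression
  dilution from exposure measurement error.
- **Reporting**: 95% CIs are estimate ± 1.96·SE throughout; gram conversion
  multiplies SD-scale estimates and CI bounds by the grams-per-outcome-SD
  constant (default 484 g) and rounds half away from zero for display.
  Internal values stay at full precision.
- **Guards**: Egger, median and mode refuse L < 3 (the pipeline marks them
  "not run" rather than failing the study); IVW with L = 1 degrades to the
  Wald ratio with a warning; Wald ratios require β̂_X ≠ 0.

## Harmonization

Exposure and outcome tables are matched by rsid (after applying a
config-supplied LD-proxy map; no online LD lookup). Swapped alleles negate
the outcome beta exactly once and reflect its allele frequency; strand flips
are resolved by complementing before comparison. Palindromic (A/T, C/G)
SNPs carry no strand information in their allele labels: they are aligned by
allele frequency when both EAFs are available and both fall outside the
ambiguity band [0.42, 0.58], and dropped when an EAF is missing on either
side. The two policies differ only inside the band: `eaf_infer` drops
band-interior SNPs, `drop_if_no_eaf` (the default) keeps the frequency
alignment with a warning. When a proxy substitutes a different variant the
allele labels are not comparable and the supplied orientation is trusted.
Every exposure SNP appears exactly once in the output with a status
(kept / flipped / dropped_palindromic / dropped_missing /
dropped_proxy_unresolved), so harmonization decisions are fully auditable.

## Conditional (COJO-style) estimation

For a target SNP t and conditioning set C, the joint least-squares system is
rebuilt from marginal statistics: X'X ≈ n · r_jk·√(v_j v_k) with
v_j = 2p_j(1−p_j), X'y_j ≈ n·v_j·β̂_j, y'y = n (phenotypes are assumed
SD-standardized — all traits in this problem are). The conditional estimate
is t's coefficient in the joint solve of {t} ∪ C, with SE from the rescaled
residual variance. Allele frequencies come from the GWAS row when present,
else from the LD reference. A collinearity guard rejects targets with
r² > 0.9 against any conditioning SNP (non-identifiable conditioning, which
also covers self-conditioning). Stepwise model selection is out of scope.
With r = 0 the conditional estimate equals the marginal one exactly; in
simulation it matches individual-level joint regression within sampling
error, and accuracy degrades as the supplied LD departs from the GWAS
sample's true LD (tested).

## The synthetic cohort generator

The generator emulates the study design, not any particular dataset:

| parameter | default | meaning |
| --- | --- | --- |
| n_exposure_gwas | 45 576 | exposure GWAS sample (mothers/adults, disjoint from duos) |
| n_outcome_duos | 50 000 | mother–child pairs in the outcome sample |
| n_snps | 10 | independent biallelic instruments |
| allele_freq_range | [0.1, 0.9] | per-SNP effect-allele frequency, uniform |
| exposure_h2 | 0.0524 | variance of exposure explained by instruments (B12-like; folate-like runs use 0.013) |
| beta_maternal_causal | 0.146 | outcome SD per exposure SD, maternal path |
| beta_fetal_causal | −0.051 | outcome SD per exposure SD, fetal genetic path |
| pleiotropy_mode/scale | none / 0 | per-SNP direct maternal-genotype effects; `directional` draws are oriented to the exposure-raising allele so they are detectable after the standard orientation step |

Mothers are drawn at HWE; each child receives one maternal allele
(fair coin at heterozygotes) plus one population allele, giving genotype
correlation 0.5 exactly in expectation. Per-SNP exposure effects carry equal
variance shares with random signs, a_j = ±√((h²/m)/v_j). The exposure is the
genetic score plus N(0, 1−h²) noise; the outcome is
β_m·(maternal exposure) + β_f·(child's exposure genetic score) + pleiotropy
+ noise, with the noise variance solved analytically so the outcome variance
is exactly 1 in expectation — no empirical rescaling, so the configured
causal effects are exact on the SD/SD scale. Configurations whose
structural variance reaches 1 are rejected as infeasible. Exposure and
outcome cohorts use disjoint seeded streams (no sample overlap, flagged in
the truth manifest); everything is bit-reproducible from the seed.

What the generator does **not** emulate: LD between instruments (instrument
correlation is handled analytically by the conditional module instead),
frequency-dependent genetic architectures, assortative mating, dynastic
environmental transmission, non-normal noise, and exposure measurement in
pregnancy (exposure effects are generated in the same adult population the
exposure GWAS samples). Passing simulation tests therefore demonstrates
estimator correctness under the stated model, not robustness to those
real-data features.

The exposure-side GWAS is a vectorized closed-form per-SNP simple
regression; the outcome side is the closed-form per-SNP duo joint
regression. Both have statsmodels-based counterparts in the analysis
modules, and tests assert the two routes agree to 1e-8, keeping
implementation and oracle independent.

## Numerical choices and degenerate inputs

- p-values are clipped to (0, 1]; degenerate bootstrap distributions floor
  the SE at the smallest positive float rather than zero.
- Mode bandwidth falls back to 1e-8 when the ratio spread is zero (point
  mass), so the estimate equals the common ratio.
- The I²_GX of identical exposure effects (Q_GX = 0) is reported as 0 with a
  degeneracy warning.
- Report files serialize floats at %.10g and JSON with sorted keys, making
  re-runs with the same config byte-identical.
- Per-analysis bootstrap seeds are spawned deterministically from the single
  study seed via `numpy.random.SeedSequence`.

## Problem sizes used in validation

The acceptance battery runs 200 end-to-end replicates at the default study
conditions for parameter recovery and coverage, 1000 summary-level
replicates for Q calibration, 200 for Egger intercept calibration/recovery,
and a single n = 20 000 two-SNP cohort for conditional-regression agreement
— sizes at which Monte-Carlo error is well below the tolerances being
checked while the whole battery completes in a few minutes on one CPU.

## Known limitations

- Wald-ratio SEs are first order (exposure uncertainty ignored), as is
  conventional; with the F statistics this package targets (≥ 35) the
  approximation error is negligible.
- The multiplicative random-effects floor is one of several defensible IVW
  SE conventions; fixed-effect SEs can be recovered as SE/√max(1, Q/df).
- The conditional module assumes unit phenotypic variance and per-SNP
  genotype variances 2p(1−p) (HWE); case-control or unstandardized traits
  would need rescaling before use.
- Mode estimators are unstable below ~10 instruments; the pipeline runs
  them whenever L ≥ 3 and leaves the judgement to the analyst, as the
  battery's own I²_GX and instrument-count reporting make the caveat
  visible.
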