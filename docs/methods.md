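# Methods

## Setting and model

The package implements the two-sample summary-data MR model. For SNP *j*,
γⱼ is the per-allele effect on the exposure (a standardized continuous trait,
SD units) and Γⱼ the effect on the outcome (SD units, or log-odds for a
binary disease). Under the instrumental-variable assumptions — association
with the exposure, independence from confounders, and no effect on the
outcome except through the exposure — Γⱼ = β·γⱼ for a causal effect β, and
each SNP's Wald ratio Γ̂ⱼ/γ̂ⱼ estimates β. Horizontal pleiotropy adds a direct
effect αⱼ (Γⱼ = β·γⱼ + αⱼ): balanced pleiotropy (E[αⱼ] = 0, independent of
γⱼ) leaves IVW unbiased but overdisperses the ratios; directional pleiotropy
(E[αⱼ] ≠ 0) biases IVW, and under the InSIDE assumption is absorbed by the
MR-Egger intercept.

## Pipeline order and conventions

Stages run in the order: p-value screen → LD clumping → harmonization →
Steiger filter → weak-instrument filter → estimation → diagnostics →
classification. The weak-instrument filter's position is configurable
(`ScreenConfig.f_filter_stage`); the default places it last.

* **p-screen**: strict inequality p < 1×10⁻⁵ (a deliberately permissive
  exposure threshold, standard when few genome-wide-significant SNPs exist
  per metabolite).
* **Clumping**: greedy by ascending p (ties broken by chromosome, position);
  each index removes same-chromosome SNPs within ±10,000 kb with LD
  r² ≥ 0.001 against it. A pair absent from the LD table counts as
  independent — the practical behaviour when a reference panel lacks a pair.
  No proxy-SNP search is performed at any stage.
* **R² and F**: R² = 2β²·EAF(1−EAF) / [2β²·EAF(1−EAF) + 2·SE²·N·EAF(1−EAF)]
  (algebraically β²/(β² + SE²·N)) and F = R²(N−k−1)/[k(1−R²)]. Filtering is
  per-SNP with k = 1 — the only convention under which an F threshold can
  remove individual SNPs; then F ≥ F_min ⟺ R² ≥ F_min/(N−2+F_min), and after
  a p < 1×10⁻⁵ screen the per-SNP F is automatically ≳ 19.5 (F ≈ z² at large
  N), so the F < 10 rule only bites when the p-screen is relaxed. The joint
  F of a whole set (k = its size, R² summed) is exposed separately.
* **Harmonization**: outcome records are aligned to the exposure's allele
  orientation; swapped alleles negate Γ̂ and complement the allele frequency;
  strand-complement reconciliation is attempted before declaring a mismatch
  (toggleable). Palindromic SNPs are removed *unconditionally* rather than
  rescued by allele-frequency comparison — the stricter, assumption-free
  choice. Removal reasons (absent from outcome / palindromic / mismatched /
  missing values / Steiger) partition the removed set.
* **Steiger filter**: a deterministic per-SNP comparison — drop SNP *j* when
  r²_out,j > r²_exp,j, both computed with the same R² formula. No z-test on
  the difference is performed; the filter is a directionality guard, not a
  hypothesis test. For binary outcomes the outcome-side R² is a log-odds
  pseudo-R², adequate for the comparison but not a variance decomposition.
* **Duplicate markers** in a source file keep the smallest p-value
  (deterministic "most significant" convention); coordinates are 1-based;
  indels and multi-character alleles are rejected at read time.

## Estimators

* **IVW** is weighted least squares of Γ̂ on γ̂ through the origin with
  weights 1/se_Γ², identical to the inverse-variance-weighted mean of Wald
  ratios with weights γ̂²/se_Γ² (asserted numerically in the tests). The
  default variant is multiplicative random effects: the SE is multiplied by
  max(1, √φ̂²) with φ̂² the weighted residual mean square on J−1 df. The floor
  prevents under-dispersion from shrinking the SE; a fixed-effect variant is
  available by flag. Inference is normal; a single SNP falls back to the
  Wald ratio with the first-order delta-method SE.
* **MR-Egger** re-orients each SNP so γ̂ⱼ > 0, fits the same weighted
  regression with an intercept, scales both SEs by max(1, √φ̂²) on J−2 df and
  uses t(J−2) for p-values and CIs. A design with all γ̂ⱼ equal is collinear
  and raises a typed degenerate-design error.
* **Weighted median**: ratios sorted ascending, cumulative midpoint weights
  sⱼ = Σᵢ≤ⱼwᵢ − wⱼ/2 (normalized), linear interpolation at s = 0.5. Weights
  are γ̂ⱼ²/se_Γⱼ², the leading-order inverse variance of the ratio. The SE is
  the SD of the estimate over parametric resamples γ* ~ N(γ̂, se_γ),
  Γ* ~ N(Γ̂, se_Γ) (default 1000; seed mandatory).

The exact random-/fixed-effect variant and median weighting differ across MR
software; the choices above follow the prevailing defaults of widely used
two-sample MR tooling and are recorded here as this package's conventions.

## Diagnostics

* **Cochran's Q** uses the fixed-effect IVW centre (re-estimated on whatever
  set it is given — a guard test ensures a leave-one-out Q is never computed
  against the full-set centre) and an upper-tail χ²(J−1) p-value. When only
  the outcome carries estimation noise, Q is exactly χ²(J−1); with a nonzero
  causal effect, exposure-side noise adds a term β²·se_γ²/γ̂² per ratio that
  the weights ignore, so Q (correctly) reports heterogeneity that grows with
  β² — the multiplicative random-effects SE absorbs it.
* **MR-PRESSO global**: observed RSS = Σⱼ wⱼ(Γ̂ⱼ − β̂₍₋ⱼ₎γ̂ⱼ)² with
  leave-one-out fixed-effect slopes and wⱼ = 1/se_Γⱼ²; the null distribution
  is built by redrawing γ* and Γ* from their estimated sampling laws and
  recomputing the statistic, leave-one-out slopes included. P-values use the
  (1 + exceed)/(1 + n_sim) convention, so zero is unattainable; per-SNP
  outlier p-values are Bonferroni-adjusted across SNPs, and the
  outlier-corrected IVW re-fit (distortion-style follow-up) is available but
  not part of the screening gates. Draws are made in canonical SNP order, so
  the result is invariant to input permutation under a fixed seed.
* **Leave-one-out** flags a SNP whose removal flips the IVW sign or moves
  its p-value across α.

## Two-tier classification

Tier 1 (*Bonferroni*): IVW p < α/n_exposures; the correction is per outcome
over the exposure panel (0.05/1400 = 3.571×10⁻⁵ at the defaults), not joint
over outcomes. Tier 2 (*nominal*): all three estimators p < α **and**
direction-consistent **and** Q, Egger-intercept and PRESSO p-values all > α.
Direction consistency is enforced globally for coherence. A diagnostic that
cannot run (e.g. PRESSO below 4 SNPs) passes vacuously but is recorded in
the report's `skipped` list. Pairs losing all SNPs at any stage are
`skipped` with the stage named.

## Synthetic-data generator

What it emulates: a standardized-metabolite exposure GWAS of n = 8,299 and a
large outcome GWAS (default 2×10⁵–5×10⁵; binary outcomes on the log-odds
scale with SEs inflated by 1/√(cf(1−cf)) for case fraction cf), with
per-SNP SEs 1/√(2N·MAF(1−MAF)), MAF ~ Uniform(0.05, 0.5), exact p-values,
random allele labelling and strand reporting (10% complementary strand, 10%
palindromic pairs), LD blocks in which tag SNPs carry √r²-attenuated
effects, and non-overlapping exposure/outcome samples (independent errors).

Instrument effects are drawn through per-SNP strength targets
zⱼ ~ Uniform(10, 40), γⱼ = zⱼ·se_γⱼ, giving per-SNP F ≈ z² ∈ [10², 1.6×10³]
— the strongly selected mQTL regime that metabolite screens retain after an
F filter. A zero-centred γ prior pushed through the p < 1×10⁻⁵ screen would
leave mostly near-threshold instruments whose winner's-curse/regression-
dilution attenuation none of the three estimators corrects; strength targets
let calibration and recovery studies measure the estimators rather than that
selection artifact. The `weak_instruments` preset lowers the targets to
straddle F = 10. Direct effects αⱼ are drawn in the exposure-increasing
orientation (Γ = βγ + α with γ > 0 before random allele re-coding), so
"directional" pleiotropy remains directional after MR-Egger's γ̂ > 0
re-orientation — with sign-symmetric γ and orientation-agnostic α, any
directional mean would cancel to balanced.

What it does **not** emulate: correlated effect-estimate errors among
LD-linked SNPs (summary stats are drawn independently; the LD table drives
clumping only), allele-frequency sampling noise, population stratification,
sample overlap, metabolite-ratio construction, or cohort meta-analysis.
Passing calibration here therefore shows the estimators and filters behave
correctly under the stated sampling model, not that real-cohort artifacts
are handled.

Scenario presets fix the study conditions: `null` (26 instruments, β = 0),
`causal` (β = 0.2, 50 instruments, n_out = 5×10⁵), `balanced_pleiotropy` /
`directional_pleiotropy` (β = 0.1, α-spread 0.005, directional mean 0.01 —
about 2.7× the outcome SE, detectable but not trivial at 26 instruments),
`weak_instruments`, and `one_outlier` (one instrument displaced by 10 outcome
SEs). The `causal` preset uses singleton LD blocks: a design-phase study
showed that with tag SNPs present, greedy clumping occasionally selects a
winner's-curse-inflated tag as the index (~20% of blocks at these strengths),
attenuating Wald ratios by ~0.7% — material relative to the 0.0012 IVW SE at
n_out = 5×10⁵ and a real phenomenon of reference-panel clumping, but a
selection artifact rather than an estimator property, so the recovery
scenario excludes it and this note records it as a known limitation.

## Problem sizes and numerical choices

The standing studies use 1000 pipeline replicates for null calibration
(MR-PRESSO at n_sim = 200 there; default 1000 elsewhere), 200 for causal
recovery, and 150 per pleiotropy mode — sizes at which the Monte-Carlo error
of a 5% rejection rate is ~0.7% and the whole battery completes in tens of
seconds on one CPU. Screen-level reproducibility comes from per-pair
sub-seeds derived via a seed sequence from (screen seed, pair index), fixed
float formatting (%.17g on data tables for exact round trips, %.10g on
report tables) and timestamp-free outputs. Strict p/z validation flags a
record when the stated p differs from 2Φ(−|β̂/se|) by more than 1×10⁻⁴
absolutely *and* 5% relatively. Degenerate inputs are typed signals, not
crashes: empty instrument sets, too-few-SNP methods and collinear Egger
designs downgrade to skipped/partial pair results inside the screen.

## Known limitations

* Steiger uses a point comparison, not a test; near-equal variances are
  decided by the noisy point estimates.
* Binary-outcome R² (Steiger) and the log-odds effect scale are
  approximations inherited from logistic GWAS summary statistics.
* Weak-instrument attenuation of IVW (NOME violation) is measured by the
  studies but not corrected; with the default strength targets it is < 0.2%
  of the effect.
* The LD table is consumed as given; no reference-panel computation beyond
  the dosage-matrix helper is provided.
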