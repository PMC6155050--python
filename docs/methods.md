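# Methods

`mrcausal` implements a bidirectional two-sample Mendelian randomisation
(MR) analysis stack: instrument construction from GWAS summary statistics,
four complementary causal estimators, the diagnostics that qualify them,
and a one-sample polygenic-score two-stage-least-squares (2SLS) follow-up.
This note records the statistical model, the defaults and why they were
chosen, the numerical decisions, and what the synthetic-data studies do
and do not demonstrate.

## Model and assumptions

For SNP *j*, let γ̂ⱼ (SE σ_Xⱼ) be its estimated per-allele effect on the
exposure and Γ̂ⱼ (SE σ_Yⱼ) its estimated effect on the outcome, both
oriented to the same effect allele. Under the instrumental-variable
assumptions (relevance, independence from confounders, effect on the
outcome only through the exposure), the generative model is

    Γⱼ = β · γⱼ + αⱼ,

with β the causal effect and αⱼ a direct (horizontally pleiotropic)
effect, zero for a valid instrument. The per-SNP Wald ratio Γ̂ⱼ/γ̂ⱼ has
first-order standard error σ_Yⱼ/|γ̂ⱼ| (the exposure-side error σ_Xⱼ is
second-order when instruments are strong; the NOME diagnostics below
handle the case where it is not).

The four estimators trade power for robustness to αⱼ ≠ 0:

* **IVW (multiplicative random effects)** — the inverse-variance-weighted
  mean of Wald ratios, equivalently a zero-intercept weighted regression
  of Γ̂ on γ̂ with weights σ_Y⁻². Residual overdispersion φ = Q/(J−1)
  inflates the fixed-effect SE by √max(1, φ); the floor at 1 means
  homogeneous instrument sets are never rewarded with a *smaller*-than-
  fixed-effect interval. Consistent when pleiotropy is absent or balanced.
* **MR-Egger** — the same weighted regression with a free intercept; the
  slope is consistent under directional pleiotropy provided InSIDE holds
  (αⱼ independent of γⱼ), and the intercept estimates the mean direct
  effect. Requires exposure-positive orientation (γ̂ⱼ ≥ 0), applied once
  at harmonisation. Inference uses t(J−2); the overdispersion inflation
  applies to both coefficients.
* **Weighted median** — the cumulative-midpoint interpolated median of
  Wald ratios; consistent while valid instruments hold more than half the
  total weight.
* **Weighted mode** — the maximiser of a weighted Gaussian kernel density
  over the ratios; consistent while the largest group of instruments
  sharing a ratio is the valid one (plurality validity). Bandwidth is the
  Silverman-style rule 0.9·min(sd, MAD/0.6745)·J^(−1/5) times a
  `bandwidth_multiplier` knob (default 1); when one of sd/MAD is zero the
  other is used, and identical ratios short-circuit to that value.

Median and mode SEs come from a parametric bootstrap: γ̂ⱼ and Γ̂ⱼ are
redrawn from normal(observed, SE), the estimator recomputed, and the
standard deviation over `n_boot` draws (default 1000) taken under a
mandatory seed. This is the construction the estimators' own literature
uses; note that because the observed values already contain estimation
noise, bootstrap SEs are mildly conservative — measured against the true
sampling SD over 400 simulated replicates the ratio is ≈1.12 for the
median and ≈1.28 for the mode, so their 95% intervals over-cover (≈0.97
and ≈0.99+ under clean 50-instrument simulations) while IVW and Egger SEs
are within ~4% of truth. This conservatism is a property of the method,
not a defect we correct.

## Instrument construction

* **Selection**: p < 5×10⁻⁸ for well-powered exposures; a liberal
  5×10⁻⁵ option exists for traits with few genome-wide hits.
* **Clumping**: greedy by p-value (PLINK-style) with defaults r² ≤ 0.001
  within 10 000 kb. LD comes from a pairwise r² table or a small dosage
  panel (squared Pearson correlation). A within-window pair missing from
  the LD source follows a policy flag: `strict` errors, `permissive`
  assumes r² = 0 with a warning.
* **Proxies**: optional; the best outcome-side proxy with r² ≥ 0.8,
  ties broken by smaller p then lexicographic id. Off by default because
  an LD source may be absent.
* **Harmonisation**: identical allele pairs kept; swapped pairs sign-
  flipped; strand complements resolved before declaring a pair
  incompatible. Palindromic (A/T, C/G) SNPs are retained only when both
  files report effect-allele frequencies, both minor-allele frequencies
  are below 0.3, and the frequencies identify the same minor allele —
  requiring all three is the conservative reading of frequency-based
  strand alignment; SNPs failing any are dropped. Finally retained
  records are oriented so γ̂ⱼ ≥ 0 (flipping Γ̂ⱼ, allele labels and
  frequencies in tandem), which makes the Egger intercept well defined.
  Every input SNP keeps an action tag so the provenance of the instrument
  set is auditable.

## Diagnostics

* **Cochran's Q / I²** on the Wald ratios about the fixed-effect IVW
  estimate; p from χ²(J−1), I² = max(0, (Q−df)/Q).
* **I²_GX (NOME)** — the regression-dilution statistic on the exposure
  betas; values below 0.9 trigger SIMEX correction of the Egger fit, the
  conventional threshold, exposed as a parameter.
* **SIMEX** — for λ ∈ {0.5, 1, 1.5, 2}, B pseudo-datasets (default 1000,
  refused below 100) add normal(0, λσ_Xⱼ²) noise to γ̂ⱼ; the mean Egger
  slope/intercept per λ is fitted with a least-squares quadratic in λ
  (including the naive λ = 0 point) and extrapolated to λ = −1, the
  zero-measurement-error limit. Variances are extrapolated the same way
  using per-λ totals (mean model-based variance plus between-simulation
  variance; the naive variance at λ = 0), falling back to the naive SE if
  the extrapolated variance is non-positive. With a degenerate λ grid the
  naive Egger fit is returned unchanged.
* **MR-PRESSO** — observed residual sum of squares RSSⱼ =
  wⱼ(Γ̂ⱼ − β₋ⱼγ̂ⱼ)² with β₋ⱼ the leave-one-out IVW estimate; the global
  statistic ΣRSSⱼ is compared against `n_sim` parametric simulations
  (Γ̂ⱼ* ~ normal(β₋ⱼγ̂ⱼ, σ_Yⱼ²), leave-one-out estimates recomputed per
  simulation). Per-SNP outlier p-values are empirical, Bonferroni-
  adjusted, flagged below `sig` (default 0.05). Empirical p-values are
  (1 + exceedances)/(1 + n_sim), so the resolution is 1/(n_sim+1) and no
  p is exactly zero. The distortion test bootstraps the non-outlier set
  (1000 draws with replacement) and reports the two-sided empirical
  p-value of the full-set estimate under the bootstrap distribution of
  the corrected estimate; the corrected estimate is flagged for reporting
  when global and distortion tests are both significant. All SNPs flagged
  is an error, not an estimate.
* **Leave-one-out** IVW, sorted by influence; **funnel data** (ratio vs
  precision) with a precision-weighted regression slope as a simple
  asymmetry test (no test below 3 SNPs); **power** via the asymptotic
  non-centrality NCP = n·R²·β² (scaled by case-fraction variance for
  binary outcomes).

## Polygenic-score 2SLS follow-up

The allele score is Σₖ wₖ·gᵢₖ with external GWAS betas wₖ and effect-
allele dosages gᵢₖ (misaligned coding contributes wₖ(2−gᵢₖ)), z-scored
over the sample. Instrument strength is the score's partial F (1 df) and
incremental R² from the first stage. The causal estimate is conventional
2SLS — exposure on score plus covariates, outcome on fitted exposure plus
covariates — with homoskedastic IV SEs by default and a
heteroskedasticity-robust option; a first-stage F below 10 produces a
prominent warning, never a suppressed estimate. Likert outcomes are
treated numerically (the follow-up's linear-regression convention);
"don't know"-type categories are coded missing upstream and every model
is complete-case (the conservative choice; no imputation). Stratified
estimates rerun 2SLS within sex strata or a median split (computed on the
analysis sample; ties to the lower stratum), dropping the stratifying
variable from the within-stratum covariates.

## Synthetic data

`simulate_two_sample` draws γⱼ ~ truncated normal, direct effects αⱼ per
regime (`none`, `balanced` μ=0, `directional` μ≠0, `inside_violating`
with αⱼ coupled to γⱼ), sets Γⱼ = βγⱼ + αⱼ, and observes both with noise
σ ∝ 1/√(2f(1−f)n) per the standard per-allele variance approximation;
`overlap_rho` correlates the two error streams to emulate participant
overlap between GWAS. Alleles, frequencies (identical in both files) and
positions are generated so files round-trip through the readers; a
configurable fraction of SNPs is palindromic to exercise harmonisation.
`invalid_fraction` sets how many SNPs receive a direct effect (1 = all,
the natural reading of the balanced/directional regimes).

`simulate_cohort` draws Binomial(2, f) genotypes, builds a unit-variance
exposure whose genetic share equals `score_r2` (default 0.018, a
realistic polygenic-score strength for an adiposity trait) plus an
unobserved standard-normal confounder, and a latent outcome
β·exposure + confounder effect + noise, optionally discretised onto a
1–6 Likert scale. Covariates mimic a middle-aged population cohort (age
~ N(56.87, 8.00), 54% female, 10 standard-normal PCs). The designed OLS
bias is the product of the confounder's two loadings (0.5 × 0.3 = 0.15 by
default), so recovery studies know both the causal truth and the exact
confounded value. What the generator does **not** emulate: LD between
score SNPs, genotype uncertainty, realistic allele-frequency spectra,
selection/participation bias, or non-linear exposure effects — so passing
recovery tests demonstrate correctness of the estimators under their own
assumptions, not robustness to those real-data complications.

## Simulation studies and problem sizes

The `calibration` module packages the recurring Monte-Carlo studies; the
reproduction script and the test suite both call it, so every reported
number is recomputed on demand. Design sizes: CI coverage and pleiotropy
bias at J = 50 strong instruments × 1000 replicates (bootstrap SEs at 200
draws per replicate, enough that bootstrap noise moves coverage by well
under half a point); Cochran's Q null at 2000 replicates; MR-PRESSO null
at 500 and planted-outlier recovery at 200 replicates (J = 50, outlier
ratio 10× the median ratio); weighted-median breakdown at J = 100
equal-weight instruments with GWAS n = 5×10⁷ so the 49%-vs-60% boundary
is sharp; SIMEX at J = 100, exposure GWAS n = 5000 (I²_GX ≈ 0.35, a
heavy-noise regime where the attenuation signal dominates extrapolation
noise) × 200 replicates; the confounded-cohort 2SLS study at n = 10 000 ×
1000 replicates. At exactly 49% invalid weight the weighted median sits
at the 0.5/0.51 quantile of the valid cluster — an offset of about two
ratio-SEs that shrinks with GWAS noise; the breakdown study therefore
checks a small absolute tolerance (|mean − β| < 0.01) rather than a
vanishing one, against a departure larger than 0.2 at 60%.

## Numerical choices

Normal reference for IVW/median/mode p-values, t(J−2) for Egger; single-
SNP input degenerates to the Wald ratio (tagged `wald`). The mode
maximiser uses a 512-point grid refined by bounded scalar minimisation
with a tolerance proportional to the grid span (so estimates are scale-
equivariant to floating-point accuracy); inside the bootstrap a 256-point
grid without refinement is used, a resolution well below the bootstrap
SD. All stochastic procedures require an explicit seed — there is no
silent global RNG — and are bit-reproducible given one. Empirical
p-values never return 0. Degenerate cases (zero bandwidth, Q_GX = 0,
rank-deficient Egger design, zero-variance score, collinear covariates,
all-outlier PRESSO) raise or warn explicitly rather than returning
silently wrong numbers.

## Known limitations

No multivariable MR, Steiger filtering, or contamination-mixture
estimators; no LD-aware genotype simulation beyond what clumping tests
need; no liftover between genome builds; ordinal outcome models are out
of scope (Likert treated as continuous). The median/mode bootstrap
conservatism documented above means their intervals are honest but wide;
consumers wanting exact nominal coverage for those two estimators should
treat the intervals as upper bounds on uncertainty.
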