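# Methods

## Covariance-structure engine

Models are written in the all-y LISREL form. The structural node set
collects the latent variables and every observed variable that takes part in
a regression; such observed variables get a unit loading and a zero
measurement residual, so the implied covariance is always

Sigma(theta) = Lambda (I − B)^-1 Psi (I − B)^-T Lambda^T + Theta.

Free parameters carry labels; cells sharing a label are one parameter, which
is also how cross-group equality constraints are expressed in two-group
models.

**Estimation.** The fit minimizes `sum_g (n_g − 1) F_ML(S_g, Sigma_g)` with
the analytic gradient (checked against finite differences in the tests),
using L-BFGS-B with variance parameters bounded below at 1e-6, followed by a
Fisher-scoring polish with step halving. Convergence requires a projected
gradient max-norm below 1e-6 on the per-observation scale; up to five
jittered restarts are attempted otherwise, and non-converged fits are
flagged rather than repaired. Start values: loadings 0.7·SD(indicator),
variances 0.5·sample variance, paths and covariances 0. A variance at the
floor is reported as a Heywood warning. Sample covariances use the n−1
divisor and `chi2 = (n−1) F` — the convention that reproduces the published
chi-square values this pipeline is benchmarked against.

**Fixed-x convention.** Observed exogenous predictors (the neural regressors
of the MIMIC models, age in the mediation models) have their variances and
covariances frozen at the sample values; these moments count neither as free
parameters nor as fitted moments. Degrees of freedom are therefore
`sum_g [p(p+1)/2 − q(q+1)/2] − #free`, with q the number of fixed-x
variables. This is what yields the analytic df ladder (8, 9, 24, 32, 12, 1,
48) of the model catalog.

**Robust corrections.** Standard errors use the Huber–White sandwich
A⁻¹BA⁻¹ with A the expected information and B the outer product of
per-observation score contributions. The test statistic is mean-scaled:
c = tr(UΓ)/df with Γ the empirical fourth-moment matrix of vech(zzᵀ) and U
the normal-theory weight matrix residualized on the model derivatives —
including pseudo-derivative columns for the fixed-x moments, so the
projection rank matches the df count. In two-group models the moment blocks
enter block-diagonally with derivatives scaled by sqrt(n_g − 1). Both
corrections need raw data; covariance-only input downgrades to naive SEs and
c = 1, with a note recorded on the fit.

A subtlety the tests encode: independent non-normal *residuals* do not
inflate the ML chi-square of a factor model (the free variances absorb the
kurtosis), so the heavy-tail check uses an elliptical (shared random scale,
multivariate-t) contamination, where the scaled statistic demonstrably
recenters at the model df.

**Fit indices.** RMSEA uses `sqrt(G · max(chi2 − df, 0)/(df · N))` with N the
total sample size, and a 90% CI from inverting the noncentral chi-square —
the convention that reproduces all published values here, including the
0.252 of the one-factor model that discriminates N from N−1. CFI uses a
diagonal (free variances only) baseline; SRMR is the RMS of standardized
residuals including the diagonal; AIC = −2 logL + 2 npar on the
Wishart-consistent likelihood, so `chi2 = 2(logL_sat − logL)` holds to
numerical precision.

**Comparisons and modification indices.** Nested comparisons use the scaled
difference `T = (chi2_r − chi2_f)/cd`, `cd = (df_r c_r − df_f c_f)/(df_r −
df_f)`, falling back to the plain difference if cd ≤ 0. Modification indices
are 1-df score tests computed in the expanded per-cell parameter space:
`MI = g² / (2 h̃)` with g the gradient along the candidate direction and h̃
the Schur complement of the expected Hessian; candidates cover fixed
cross-loadings, absent structural paths, residual and disturbance
covariances, and — in constrained multigroup models — the splitting of one
cell out of an equality set. Directions whose Schur complement is below
1e-6 of the raw curvature are reported as non-identified and skipped (the
residual covariance between the only two indicators of a factor is the
canonical example).

## Synthetic cohort generator

The generator emulates a population-based lifespan cohort: age uniform on
[18, 88] (the flat design of a population-based sample), six neural measures
declining with age at different rates, two correlated cognitive factors
receiving paths from age and from specific neural variables, and Gaussian
indicators. Defaults are calibrated to the published estimates:

- age → neural correlations −0.20 (BA10), −0.18 (MD), −0.77 (FM), −0.51
  (ATR); the control regions use −0.30 (temporal pole) and −0.55 (forceps
  major), plausible values chosen once since no estimates are printed.
- neural → factor paths 0.156 (BA10→fluid), 0.131 (FM→fluid), 0.155
  (ATR→multitask) — the standardized mediation-model values; all other
  neural→factor paths are zero by construction.
- latent factor correlation 0.325.
- **Score attenuation.** The published age–cognition correlations (−0.67,
  −0.29) are factor-*score* correlations, which are shrunk relative to the
  latent ones. The calibration solves a 2×2 linear system so that the
  analytic Thomson-score correlations hit −0.67/−0.29; the implied latent
  correlation (≈ −0.73) then reproduces the mediation model's total effect
  (c' ≈ −0.59) without further tuning — the two published quantities are
  mutually consistent once attenuation is accounted for.
- loadings 0.80/0.75/0.70/0.65 (Cattell) and 0.80/0.55 (reversed TTM,
  #tasks): realistic values chosen once; the published loadings are not
  printed in the text.
- within-modality residual neural correlations (GM–GM 0.50, WM–WM 0.45,
  0.30–0.35 to the controls): real structural measures correlate beyond
  shared ageing; without this the single-PFC-factor control model would not
  face a realistic covariance structure. The BA10–FM (cross-modality) pair
  is left at its age-induced value, which is what the fluid mediation model
  assumes.
- heteroscedasticity: behavioural residual SD is multiplied by
  `1 + 0.5·(age−18)/70`, normalized so the marginal covariance matrix is
  unchanged; 0.5 makes the age-increasing spread detectable at n=567, as in
  the published Breusch–Pagan tests.

Raw units: Cattell sub-scores on their usual score scales, Hotel
total-time-misallocated stored in raw seconds (higher = worse; the model
frame reverse-codes it so multitasking loadings are positive), number of
tasks rounded to integers in [1, 5] with a Sheppard variance correction
(1/12 of a step) removed from the continuous residual so the rounded
column's covariances still match the population model, FA values kept in
(0, 1), GMV in volume-fraction units. Default cohort size 567.

What the generator does *not* emulate: bounded/skewed raw score supports
(indicators are Gaussian, matching the SEM's assumptions rather than real
task distributions), item-level task behaviour, imaging data, sex or cohort
effects, and any non-linearity in age trends. Passing tests therefore show
that the pipeline recovers the intended statistical structure, not that it
would survive every pathology of real data.

**Outlier screening** drops rows with any neural |z| > 4, with z computed
from the input table's own moments in one pass (no re-screening), mirroring
the published exclusion rule (571 → 567 with four planted extremes).

## Analysis pipeline

Stages run in the published order: outlier screen → measurement-model
comparison (two-factor vs one-factor vs hierarchical) → age effects on
Thomson factor scores (Fisher CIs, Williams test, Breusch–Pagan, classical
and HC1 sandwich regressions) → MIMIC models (full, brain-path equality
constraint, control regions present/zeroed, single-PFC-factor, GM/WM
two-factor) → mediation decompositions with percent-mediated effect sizes →
young/old multigroup models (youngest/oldest 210 — the oldest-extremes
reading of the published split — configural vs loadings+paths constrained,
modification indices on the constraints, Levene tests). Each stage's
p-value family carries Benjamini–Hochberg FDR flags at q = 0.05; family
membership is recorded in the report. Reports are JSON plus a Markdown
summary and are byte-reproducible for a given cohort and configuration.

**Hierarchical model identification.** With only two first-order factors a
higher-order factor is not separately identified. The catalog's hierarchical
model fixes both second-order loadings to 1, zeroes the first-order
disturbances and frees the second-order variance: an exact reparameterization
of the one-factor model with one redundant parameter, which is precisely the
published behavior (identical fit, AIC difference of 2). Its likelihood has
a flat direction, so standard errors for it are not meaningful and model
choice rests on AIC.

**Mediation inference.** Paths are taken from the fully standardized
solution; their covariance comes from the delta method through the
standardization map (numerical Jacobian) applied to the robust parameter
covariance. Indirect products use the multivariate delta method, with an
"inconsistent mediation" flag when indirect and total effects disagree in
sign (the percentage then leaves [0, 100]). The percent-mediated quantity is
`100·Σa_ib_i/(Σa_ib_i + c')` — the decomposition that reproduces both
published effect sizes (18.2%, 29.4%) from the printed standardized paths.
The delta-method z for a product is conservative when the true a-path is
null and the b-path is weak (the Sobel phenomenon); the calibration tests
therefore use a moderate b (0.3–0.4), where the test holds its nominal size,
and the weak-b case is asserted at its wider, conservative band.

## Numerical and test-design choices

- Simulation sizes: recovery at n=200 000 (sampling error ≈ 0.005 on
  standardized paths, comfortably inside the ±0.02 recovery bands);
  calibration tests at 500 replications of n=567; power/detection tests at
  100 replications. Problem sizes were chosen so the full suite runs in a
  couple of minutes on one core.
- The planted cross-group difference (ATR→multitask +0.5 in the old group)
  is sized to be a clearly detectable effect at n=210/group; detection is
  declared when the largest brain-path modification index identifies the
  right constraint and its scaled 1-df test exceeds 3.84.
- The scaled-difference calibration uses an interior null (factor covariance
  fixed at its true value 0.325). A boundary null (true factor correlation
  0 with a two-indicator factor) produces frequent Heywood solutions and a
  non-chi-square mixture distribution — a real phenomenon, not an engine
  defect, and deliberately not used for the size check.
- No established SEM package is bundled or required; the engine is verified
  against closed-form ML solutions (3-indicator factor model, observed-path
  models = OLS, saturated models) and against brute-force numerically
  optimized ML fits with an independently coded implied-covariance routine.

## Known limitations

Covariance structures only (no mean structure, no missing-data FIML, no
categorical estimators, no Bayesian option). Covariance-only input disables
the robust corrections. Two groups at most in multigroup models. The
generator's Gaussian indicators understate the tail behavior of real
behavioural scores; the Satorra–Bentler machinery is exercised with explicit
non-normal contamination in the tests instead. Cross-sectional mediation
estimates describe covariance decomposition, not within-person change.
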