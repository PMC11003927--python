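# Methods

## Model

The response for one tooth is the natural log of its soft-tissue fraction,
`y = ln((V_low_soft + V_high_soft) / V_total)`, from T2-intensity
segmentation (defaults: intensities 0–63 hard tissue, 64–100 low-signal
soft, ≥101 high-signal soft, on 0.37 mm iso-voxels; the helper converts
voxel counts to ml). The ratio is scale invariant, so only relative volumes
matter; records with zero soft volume have no defined response and are
excluded with a warning rather than mapped to −∞.

Per tooth, `y | a, s ~ Normal(β₀ + β₁a + β₂m + β₃am, σ²/w(a))` with
`m = 1[s = M]` (female is the reference level throughout). Four sex
structures are supported — common line (`COMMON`), sex intercept offset
(`ADDITIVE`), sex-specific slopes with common intercept (`SLOPES_ONLY`),
and both (`FULL_INTERACTION`) — crossed with three variance weights
`w(a) ∈ {1, 1/a, a}`. Age enters uncentred, in decimal years.

### The variance-weight convention

A printed weight such as "1/age" does not by itself say whether variance is
multiplied or divided by age. We adopt the weighted-least-squares
convention used by `lm(..., weights=)`-style software: the observation
weight is inversely proportional to the residual variance, so
`Var(y|a) = σ²/w(a)` and `w = 1/a` means variance grows linearly with age.
The opposite reading is available everywhere via `invert_weights=True`
(CLI: `--invert-variance-weights`) for sensitivity analysis, and the CLI
logs which convention a fit used.

### Estimation per tooth

Betas are estimated by weighted least squares (statsmodels `WLS`), which is
the ML estimator for this model; `σ̂²` is the ML (divide-by-*n*) weighted
mean squared residual so that the reported log-likelihood and
`AIC = 2k − 2ℓ̂` are internally consistent, with `k` = free betas + 1 for
σ. REML is deliberately not offered. AIC selection over the 4×3 candidate
grid breaks exact ties toward fewer parameters, then a fixed enumeration
order. A packaged default configuration ships for all twelve molars.

Of note for users of the selection machinery: when the generating process
truly has no sex terms, AIC still retains an over-parameterised sex
structure in a sizeable minority of datasets — the three nested likelihood
ratio statistics involved are asymptotically χ² and exceed their 2·Δk
penalties with combined probability ≈ 0.22 regardless of sample size. This
is a property of AIC itself, not a defect of the fit.

### Joint model

One tooth per molar class (1st/2nd/3rd) is combined into a multivariate
Gaussian whose diagonal reproduces the per-tooth variances and whose
off-diagonal is `ρ_tu·√(Var_t(a)·Var_u(a))`, with a single correlation per
class pair shared across sexes. Missing teeth are handled by exact Gaussian
marginalisation: a participant contributes the marginal density of the
subset they possess; no imputation. All parameters are maximised jointly
(L-BFGS-B with a Nelder–Mead polish on non-convergence; tolerance 1e−8 on
the log-likelihood), with σ on the log scale and ρ through the Fisher
z-transform; the start is the independent per-tooth fit with ρ = 0, making
the optimisation deterministic. Correlation triples whose 3×3 matrix is not
positive definite are rejected by a −∞ log-likelihood (a large finite
penalty inside the optimiser) rather than reparameterised through a factor
decomposition, keeping the ρ's directly interpretable. A `two_stage` mode
(freeze the per-tooth fits, maximise over ρ only) is provided for
comparison; the one-stage joint MLE is the primary estimator.

Identifiability guards: sex structures require both sexes present;
correlations require at least one participant holding ≥2 of the mapped
teeth; rank-deficient designs and optimiser non-convergence raise explicit
errors, never a silent partial result.

## Prediction

The posterior age density under a uniform prior on [14, 23] years is the
observation's (possibly marginal) Gaussian likelihood evaluated along the
age grid and normalised by the trapezoidal rule. Grid step defaults to
0.005 y, which resolves two-decimal percentiles with an order of magnitude
to spare (halving the step moves quartiles by < 1e−3 y in the test suite).
Quantiles interpolate the discrete CDF linearly; `P(age > 18)` is the
complement of the interpolated CDF, treated as a strict inequality
(immaterial on a continuous posterior). Sex is treated as known at
prediction time. The likelihood is computed in log space and shifted by its
maximum before exponentiation; an observation whose likelihood underflows
everywhere on the grid raises an error naming the observation.

Hypothetical observations place six equally spaced points from the minimum
to the maximum observed response per tooth and sex and keep the four
interior ones, coloured black/red/green/blue in descending response order
(blue = most negative = oldest-looking). `compare_combinations` evaluates
every nonempty subset of the model's classes (7 for a three-class model) ×
4 colours = 28 rows of (q25, q75, IQR, P>18).

## Synthetic cohorts

The generator emulates the study design the model targets: 65 female and
34 male participants, ages uniform on [14, 24], responses drawn from the
truth model's multivariate normal at each participant's age/sex, and
per-class missingness (0.12, 0.06, 0.32 for 1st/2nd/3rd molars) reproducing
molar-level availability of about 87/93/67 out of 99 (third molars are
often excluded or congenitally absent). Volumes are reconstructed with the
total fixed at 1 ml and the soft volume split evenly between the low- and
high-signal classes — only the ratio informs the model, so synthetic
volumes must not be read anatomically. The packaged truth parameters are a
synthetic stand-in chosen once for realism (negative slopes steepest and
residual scatter relatively smallest for the 3rd molar; correlations
0.620/0.430/0.598, highest between developmentally adjacent classes); they
are not estimates from any real cohort, so passing tests demonstrate
internal consistency and estimator behaviour, not agreement with real
dental data. Real data also differ in ways the generator ignores: ages are
not uniform in practice, segmentation noise is absent, missingness is
independent of age here but age-related in reality (third molars erupt
late), and volumes are exact rather than rounded.

`recovery_experiment` runs seeded simulate→fit cycles and reports bias and
RMSE per parameter; fit failures are counted, not swallowed. At the study's
own size (n ≈ 99) correlation estimates carry standard errors of roughly
0.1–0.15; the recovery checks in the test suite therefore use n = 2000
complete cases, where each ρ̂ lands within ±0.05 of the truth.

## Numerical choices and limitations

- Collinear (zero-residual) data drive σ̂ → 0; the likelihood is reported
  as +∞-free by flooring σ̂² at 1e−300, and betas remain exact.
- The AIC tie-break (fewer parameters, then enumeration order) only fires
  on exact floating-point ties.
- Posterior quantiles assume the CDF is nondecreasing on the grid; flat
  zero-likelihood stretches interpolate to their left edge.
- The prior upper bound (23 y) is below the cohort's inclusion limit
  (24 y) by design choice of the prior; observations from 23–24-year-olds
  are therefore compressed against the prior edge.
- No non-uniform priors, no REML, no splines in age, no more than one
  tooth per molar class, and no sex-specific correlations.
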