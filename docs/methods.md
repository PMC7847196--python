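# Methods

## The growth model

`xenopower` analyses two-arm xenograft studies with the first-principles
(Mayneord) tumour growth model, in which the radius of a spherical tumour
grows linearly in time. Volumes are converted to radii via
R = (3V / 4π)^(1/3), and the observed radius of animal *i* at time *t_ij* is

    R_ij = (a_i + b_i t_ij) (1 + e_ij)

with animal-level random effects and proportional residual error:

    log a_i ~ N(μ1, σ1²)        baseline radius at randomisation (log mm)
    log b_i ~ N(μ2 + c T_i, σ2²)   radial growth rate (log mm/day)
    e_ij    ~ N(0, σ3²)         proportional measurement error

T_i is the treatment indicator (0 control, 1 treated) and c the population
treatment effect on the growth rate. A volume-scale variant replaces the
mean response by V_ij = (4π/3)(a_i + b_i t_ij)³ (1 + e_ij); because
calliper errors are made on lengths, the radius scale is the default.

The proportional error term reflects the empirical fact that the spread of
tumour-size measurements grows with the tumour: the observation density is
Normal with mean m_ij and standard deviation σ3·m_ij.

### Treatment-effect scale

Writing the effect on the mean of log b (multiplicative on the rate) keeps
the growth rate lognormal — internally consistent with the control-arm
model — but can only approach 100% tumour growth inhibition (TGI) in the
limit c → −∞. The package therefore supports two scales:

- `log_shift` (default): treated rates are multiplied by e^c on average.
  Calibrating to TGI = 100 returns the documented floor c = −20
  (treated growth ≈ e^(−20) of control, i.e. static) with a warning.
- `natural_shift`: the rate is represented by a moment-matched Normal on
  the natural scale and c shifts its mean additively; TGI = 100 is then
  exactly attainable. Simulated mean radii are floored at 10⁻⁶ mm since a
  Normal rate is sign-indefinite.

Estimation supports the log-scale effect only: a sign-indefinite rate is
incompatible with the lognormal random-effect distribution the fitter
assumes. The natural scale exists for simulation and calibration of
complete-stasis scenarios.

## Population moments, expected TGI and calibration

The population mean volume at day *t* is obtained by expanding
E[(a + b t)³] with the binomial theorem in the raw moments of the two
(log)normal effects, E[X^k] = exp(kμ + k²σ²/2); the residual term is
unbiased since E[1 + e] = 1. Model-expected TGI follows the standard
definition applied to these expectations,

    %TGI(T) = 100 · (EV_c(T) − EV_t(T)) / (EV_c(T) − EV(0)),

and `calibrate_c` root-finds (Brent) on the monotone map c ↦ expected TGI
to hit a target within 10⁻⁶ TGI points. Both are cross-checked against
Monte-Carlo oracles in the test suite.

## Simulation

`simulate_study` draws per-animal effects and proportional noise on a
measurement schedule of every 3–4 days from randomisation — days
{0,3,7,10,14}, plus {17,21} to day 21, plus {24,28} to day 28 — matching
common practice in large xenograft screens. Residual multipliers 1 + e
are resampled until they exceed 0.01 so radii stay positive. One root
seed drives a study; per-animal substreams are spawned deterministically
(`numpy.random.SeedSequence`), so studies are reproducible and arms are
exchangeable under c = 0.

## Estimation

### Mixed-effects fit

The marginal likelihood integrates the 2-d latent pair
u_i = (log a_i, log b_i) out of each animal's contribution. The integral
is approximated by a Laplace approximation around the joint mode, found
by a damped Newton iteration with analytic gradient and Hessian (the 2×2
curvature is ridged to positive-definiteness where needed; modes warm-start
across likelihood evaluations, with a cold restart whenever a stale warm
start strands the iteration). A 5-node adaptive Gauss–Hermite mode
(`integration="aghq"`, 25 abscissae centred at the mode and scaled by the
inverse curvature) serves as a cross-check; on the study sizes of interest
the two agree to well under one log-likelihood unit and the test suite
asserts that agreement.

The outer optimization runs L-BFGS-B on (μ1, μ2, log σ1, log σ2, log σ3
[, c]) with 3-point finite-difference gradients, relative-tolerance
10⁻¹², and bounds log σ ∈ [−7, 2.5] (boundary estimates are flagged).
Starting values come from per-animal least-squares lines: means and
spreads of the per-animal log intercepts/slopes, residual spread for σ3,
c = 0. Standard errors are obtained from the observed information
(central finite differences of the negative log-likelihood at the
optimum), with the delta method mapping log-σ uncertainties back to the
σ scale.

The performance-critical per-animal Newton loops are compiled with numba
(`_kernels.py`); a numerically equivalent pure-numpy path remains as a
fallback and backs the AGHQ mode.

### Pooled fit

The naïve pooled approach fits a single fixed (a, b) to all animals
(radius scale only), with the treatment effect again shifting log b. The
proportional-error residual SD has a closed-form profile estimate, so
only 2–3 parameters are optimized (Nelder–Mead). On noise-free data the
residual SD is pinned at the floor 10⁻⁶ and flagged.

### Likelihood-ratio test

Nested fits with/without c are compared via Λ = 2(ℓ₁ − ℓ₀) against
χ²₁ (c is an interior parameter, so the mixture correction for variance
components does not apply). The alternative fit is warm-started from the
null optimum with c = 0, enforcing ℓ₁ ≥ ℓ₀ up to optimizer tolerance;
small negative Λ is clipped at zero and larger negative values trigger a
warning.

## Empirical analysis

%TGI is computed from arm-mean volumes — each animal contributes its last
measurement at or before the horizon, the control baseline its day-0
measurements — and the treatment comparison is the classical unpaired
two-tailed t-test on final-day volumes (pooled-variance Student by
default; Welch available). Values above 100 (regression) and below 0
(faster treated growth) are reported as computed.

## Power engine

`run_power_cell` calibrates c to a target TGI at the horizon, simulates
`reps` studies and records the fraction with p < 0.05 (±binomial
Monte-Carlo SE). `run_power_table` evaluates the Cartesian grid
(TGI ∈ {50,100}) × (N ∈ {5,8,10,12,15}) × (day ∈ {14,21,28}) × methods,
with per-cell seeds derived from the root seed and cell index so cells
are independently reproducible. The default 1000 replicates per cell
match standard practice for two-decimal power tables; `--reps` lowers
this for desk runs, with the MC SE always reported alongside.

`significance_curve` summarises a batch analysis as the cumulative
fraction of significant studies among those with TGI ≤ x, probing the
smallest effect size a method can detect.

## Shipped parameter sets

`pdx.yaml` / `cdx.yaml` are representative, synthetic reference sets —
not estimates from any real study:

| set | μ1 | σ1 | μ2 | σ2 | σ3 |
|-----|-----|-----|-----|-----|-----|
| PDX | 1.29 | 0.10 | −2.40 | 0.50 | 0.10 |
| CDX | 1.29 | 0.05 | −2.40 | 0.15 | 0.05 |

Rationale: ~200 mm³ at randomisation (R ≈ 3.6 mm, a tight randomisation
window giving ~10%/5% baseline CV), control growth reaching ~1000 mm³ by
day 28 (b ≈ 0.09 mm/day), growth-rate CV ≈ 53% for patient-derived grafts
versus ≈ 15% for an established cell line, and ~10%/5% proportional
calliper error on the radius. These values produce the qualitative
structure expected of such designs (see below) but absolute power values
depend on them and should be re-derived from fitted control parameters
for any concrete application (`xenopower fit`).

## What the simulator does and does not emulate

The generator reproduces the statistical skeleton of a two-arm xenograft
study: lognormal baseline/growth-rate heterogeneity, proportional
measurement error, a 3–4-day schedule, and truncation at 14/21/28 days.
It does not simulate dropout (welfare-limit sacrifice of large-tumour
animals), non-linear growth phases (lag, saturation), measurement-day
jitter, or correlated baseline/growth effects. Passing tests therefore
demonstrate correctness of the methods under the model's assumptions, not
robustness to those real-data features — in real studies dropout in
particular biases final-day TGI, which is one of the arguments for
model-based analysis.

## Calibration findings baked into the tests

Two behaviours of the methods are properties, not defects, and the test
suite documents them:

- The t-test on final volumes is conservative under these conditions
  (rejection ≈ 3–4% at nominal 5%): final volumes are approximately
  cubed-lognormal, i.e. heavily right-skewed, at N = 10 per arm.
- The mixed-model LRT is mildly anticonservative across this design
  space: type-I ≈8% at the smallest design (N = 10/arm, day 14, PDX-like
  variability) and ≈6–7% at richer ones (N = 15/day 28 PDX ≈ 7.0%, CDX
  N = 10/day 14 ≈ 6.0%, each measured at 2000 replicates). The χ²₁
  reference is asymptotic and 20–30 animals is far from that limit. Null
  optimization and the integral approximation were ruled out as causes
  (warm-restart and adaptive Gauss–Hermite experiments). Practitioners
  wanting exact size at these sample sizes should permute arm labels or
  apply a small-sample correction; p-values near 0.05 deserve caution,
  while the power comparisons (model-based vs empirical) are unaffected
  in substance since the advantage at 50% TGI is far larger than the
  calibration gap.
- The naïve pooled LRT is severely anticonservative under between-animal
  growth-rate heterogeneity (≈33% type-I at the PDX-like setting):
  pooling treats within-animal repeated measures as independent. This is
  the statistical argument for the mixed-effects analysis; the pooled
  method is retained as a comparator.

## Numerical choices and degenerate inputs

- Inner Newton: gradient tolerance 10⁻¹¹·(1+|g|) with an
  expected-decrease stall exit at float resolution; ≤ 60 iterations;
  Armijo backtracking (≤ 16 halvings).
- Laplace determinant: 2×2 curvature eigen-ridged to ≥ 10⁻⁸.
- σ parameters are optimized on the log scale; estimates at the bounds
  are reported with `boundary=True`.
- Noise-free data: the pooled σ3 profile estimate is floored at 10⁻⁶,
  keeping the log-likelihood finite.
- TGI is undefined when the control arm did not grow; this raises an
  error rather than returning a number.
- Zero-variance t-test inputs: equal means give p = 1, unequal means
  p = 0 with an infinite statistic.
- Databases: non-positive volumes are rejected (counted in the log),
  fractional days floored with a warning, arm labels normalised
  case-insensitively ({vehicle, control} → control; {treatment, treated}
  → treated), anything else is an error.

## Problem sizes used by the shipped checks

The acceptance script and test suite use 1000 replicates for empirical
and mixed power/type-I cells, 600 for the secondary calibration designs,
300 for model-based cells inside comparative assertions, 500 simulated
animals for the recovery experiment and 10⁶ draws for Monte-Carlo moment
oracles.
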