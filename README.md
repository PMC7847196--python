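# xenopower

Model-based analysis and power calculation for two-arm xenograft
tumour-growth studies.

## The problem

Preclinical oncology relies on xenograft experiments: tumour-bearing mice
are randomised to a treated and a control arm, tumour volume is measured
every 3–4 days, and after 2–4 weeks the drug effect is summarised as the
percent tumour growth inhibition

    %TGI(T) = 100 · (V̄_control(T) − V̄_treated(T)) / (V̄_control(T) − V̄_control(0))

with significance from an unpaired two-tailed t-test on final-day
volumes. This convention throws away the whole time series, which costs
statistical power — and power is animals, money and time. The cost is
worst for patient-derived xenografts (PDX), whose between-animal
variability is far higher than that of classical cell-line xenografts
(CDX).

`xenopower` implements the alternative: a mechanistic growth model fitted
to every measurement, with the treatment effect tested by a likelihood
ratio, side by side with the conventional empirical analysis, plus a
simulator and Monte-Carlo power engine for comparing the two and sizing
future studies.

## The model

Assuming a spherical tumour whose radius grows linearly in time
(the first first-principles tumour growth model, due to Mayneord),
with R = (3V/4π)^(1/3):

    R_ij = (a_i + b_i t_ij)(1 + e_ij)
    log a_i ~ N(μ1, σ1²)           baseline radius, animal i
    log b_i ~ N(μ2 + c·T_i, σ2²)   growth rate; T_i = 1 for treated
    e_ij    ~ N(0, σ3²)            proportional measurement error

The marginal likelihood (random effects integrated out per animal by a
Laplace approximation, with an adaptive Gauss–Hermite cross-check) is
maximized with and without the treatment effect `c`; the nested fits are
compared by Λ = 2(ℓ₁ − ℓ₀) against χ²₁. A volume-scale variant and a
naïve pooled (fixed-effects) variant are included, as in common practice.

## Worked example

Simulate a 21-day PDX-like study whose treatment effect is calibrated to
a model-expected 50% TGI, then analyse it both ways:

```python
import xenopower as xp

params = xp.named_params("pdx")                  # representative PDX-like set
c = xp.calibrate_c(params, 50.0, 21.0)           # -> -0.456
study = xp.simulate_study(params.with_effect(c), n_per_arm=10,
                          horizon=21, seed=1)

print(xp.study_tgi(study))        # TGI 67.5% at day 21 (control n=10, treated n=10)

res = xp.fit_mixed(study)         # TumorGrowthModel(study).fit() equivalently
print(res.summary())
```

```
Linear-radius tumour growth model
==============================================
approach:  mixed      scale: radius
animals:   20         observations: 140
log-likelihood: -127.2571
converged: True
----------------------------------------------
param       estimate     std err
mu1          1.26504     0.03218
mu2         -2.12548     0.11604
sigma1       0.11865     0.02502
sigma2       0.27529     0.08229
sigma3       0.11395     0.00783
c           -0.83214     0.19815
==============================================
```

The estimated effect ĉ = −0.83 means treated tumours' radial growth rate
is e^(−0.83) ≈ 0.43× the control rate. Testing it:

```python
print(xp.lr_treatment_test(study))   # stat=14.582 p=0.0001 c_hat=-0.832
print(xp.empirical_test(study))      # t=2.343  p=0.0308 TGI=67.5%
```

Both analyses detect this effect, but the model-based p-value is two
orders of magnitude smaller — the time series carries far more
information than the final day alone. The power engine quantifies this:

```python
cell = xp.run_power_cell(params, tgi_target=50.0, n_per_arm=10,
                         horizon=14, method="mixed", reps=300, seed=0)
# vs method="empirical": ~45% power against ~22% at N=10/arm
```

and `run_power_table` evaluates the full grid
(TGI ∈ {50,100}) × (N ∈ {5,8,10,12,15}) × (day ∈ {14,21,28}) × methods.

A command line mirrors the library:

```
xenopower simulate-db --params pdx --n-studies 59 --out db.csv
xenopower analyze db.csv --horizon 14 --method empirical --method mixed
xenopower fit db.csv --study S001 --approach mixed --scale radius
xenopower power --config power.yaml --out table.csv
```

The shipped `pdx`/`cdx` parameter sets are representative synthetic
values (documented in `docs/methods.md`), not estimates from any real
study; fit your own controls with `xenopower fit` to get
application-specific numbers.

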