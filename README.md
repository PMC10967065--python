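# countcorr

Corrected covariance estimation for Poisson regression on autocorrelated
count time series, with an interrupted time-series (ITS) pipeline for
intervention evaluation.

## The problem

Daily or monthly event counts — injuries, deaths, admissions — are almost
always serially correlated, yet they are routinely analysed with a Poisson
GLM that assumes independent outcomes. Under a *parameter-driven* model the
dependence enters through a latent stationary Gaussian AR(1) process
`alpha_t` in the log mean:

    Y_t | alpha_t ~ Poisson(exp(offset_t + alpha_t + x_t' beta)),
    alpha_t ~ N(-sigma2_alpha/2, sigma2_alpha),   corr(alpha_t, alpha_{t+h}) = rho_alpha^h.

The GLM point estimate of `beta` stays consistent, but its reported
standard errors are too small, inflating the type I error of intervention
tests. The valid covariance is the sandwich

    G_n = Omega_I^{-1} + Omega_I^{-1} Omega_II Omega_I^{-1},

where `Omega_II` carries the autocovariance `gamma_w(h)` of the latent
multiplicative noise `w_t = exp(alpha_t)`. `countcorr` implements two
estimators of the nuisance parameters `(sigma2_w, rho_w)` feeding that
sandwich:

- **UB** — the classical unbiased-correction moment estimators, taking the
  lag-1 autocorrelation estimate as the truth. Slightly downward biased at
  high autocorrelation, which re-inflates the type I error.
- **MSRC** (maximum significant rho correction) — screens lags 1–5 with a
  one-sided Z test at level 0.01, root-transforms each significant lag-h
  estimate to an order-1 equivalent via the AR(1) relation, and plugs in
  the **maximum**. Conservative by construction; controls the type I error
  once the series has ≈340 points, at a small cost in power.

The package also ships the parameter-driven simulator, a Monte Carlo
harness for type-I-error/power studies on the ITS design
`x_t = (1, t, X, X(t - t0))`, and an application-grade daily-count pipeline
(harmonic seasonality, day-of-week/holiday/precipitation/temperature
adjustment, exposure offset) that reports the time-varying excess risk

    ER(t) = (exp(b_X + b_int' ns(t, 5)) - 1) x 100%

with delta-method confidence intervals under any of the three covariances.
See `docs/methods.md` for the full model, estimators and design choices.

## Worked example

```python
import numpy as np
from countcorr import (
    LatentParams, build_its_design, simulate_series, fit_poisson_glm,
    naive_covariance, ub_correct, msrc_correct, wald_test,
)

# one synthetic ITS series: n=340, intervention at midpoint, no true effect,
# latent AR(1) noise with sigma2=0.5, rho=0.8
design = build_its_design(n=340, t0=170, time_scale=340)
data = simulate_series(design, beta=(1.0, 1.0, 0.0, 0.0),
                       params=LatentParams(0.5, 0.8), seed=7)

fit = fit_poisson_glm(data)
ub, ms = ub_correct(fit), msrc_correct(fit)

j = design.intervention_col
for name, se in [("naive", np.sqrt(naive_covariance(fit)[j, j])),
                 ("UB   ", ub.se()[j]), ("MSRC ", ms.se()[j])]:
    z, p, reject = wald_test(fit.beta_hat[j], se, level=0.05)
    print(f"{name} se={se:.3f}  z={z:+.2f}  reject={reject}")
print(f"rho1 UB={ub.rho1_used:.3f}  MSRC={ms.rho1_used:.3f} "
      f"(selected lag {ms.selection.selected_lag})")
```

Output:

```
naive se=0.118  z=+0.70  reject=False
UB    se=0.446  z=+0.19  reject=False
MSRC  se=0.446  z=+0.19  reject=False
rho1 UB=0.690  MSRC=0.690 (selected lag 1)
```

The naive GLM standard error (0.118) is four times too small: on this draw
the latent process carries lag-1 autocorrelation ≈0.7, and both corrections
widen the standard error of the level-change coefficient accordingly (here
the lag-1 candidate wins the MSRC screen, so the two corrections agree; at
higher lags' dominance MSRC is strictly wider). With the corrected
covariance the intervention test keeps its nominal 5% size; with the naive
one it would reject a true null roughly two-thirds of the time at these
settings.

Command-line equivalents:

```bash
countcorr table1 --config cfg.json --reps 2000 --seed 1 --out table1.csv
countcorr power  --scenario level --reps 1000 --seed 1 --out power.csv
countcorr its    --data daily.csv --t0 2011-05-01 --method all --out er.json
```

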