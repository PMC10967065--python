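# Methods

## Model

`countcorr` targets count time series whose serial dependence enters through
a latent process rather than through lagged outcomes ("parameter-driven"
dependence):

    Y_t | alpha_t ~ Poisson( exp( offset_t + alpha_t + x_t' beta ) ),
    alpha_t ~ stationary Gaussian AR(1),  alpha_t ~ N(-sigma2_alpha/2, sigma2_alpha),
    corr(alpha_t, alpha_{t+h}) = rho_alpha^h.

Tying the latent mean to `-sigma2_alpha/2` makes `E[exp(alpha_t)] = 1`, so
`exp(x_t' beta)` stays the marginal mean and `beta` keeps its ordinary
log-rate interpretation. Writing `w_t = exp(alpha_t)`, the marginal moments
are

    E[Y_t]   = mu_t = exp(x_t' beta),
    Var[Y_t] = mu_t + sigma2_w mu_t^2,            sigma2_w = exp(sigma2_alpha) - 1,
    corr(Y_t, Y_{t+h}) = rho_w(h) / sqrt{(1 + 1/(sigma2_w mu_t))(1 + 1/(sigma2_w mu_{t+h}))},

with `rho_w(h) = (exp(rho_alpha^h sigma2_alpha) - 1) / (exp(sigma2_alpha) - 1)`.
The `alpha`-scale and `w`-scale parameterisations are exact exponential maps
of each other (`core_model.alpha_to_w_rho` / `w_to_alpha_rho`); estimation
happens on the w-scale, reporting on the alpha-scale.

## Covariance correction

The Poisson GLM point estimate `beta_hat` remains consistent under this
model; the GLM covariance `Omega_I^{-1}` (inverse Fisher information) does
not. The corrected covariance is the sandwich

    G_n = Omega_I^{-1} + Omega_I^{-1} Omega_II Omega_I^{-1},
    Omega_II = sum_{h=-L}^{L} sum_t x_t x_{t+h}' mu_t mu_{t+h} gamma_w(h),

where `gamma_w(h) = sigma2_w rho_w(h)` is the latent autocovariance and `L`
truncates the lag sum. The nuisance parameters are estimated by moment
estimators whose own bias (driven by the sampling noise of `mu_hat`) is
removed with correction factors `exp(-2 x' G x)` etc. — e.g. `mu_t^2` is
estimated unbiasedly by `mu_hat_t^2 exp(-2 x_t' G_n x_t)`.

**Circularity and the two-step scheme.** The bias corrections need `G_n`,
which needs the nuisance estimates. The package resolves this with
estimate/correct passes starting from the naive covariance; the default is
*two* passes (estimate at `Omega_I^{-1}`, correct, re-estimate at the
corrected `G`, correct again). We do not iterate to a fixed point by
default: at high autocorrelation the map `G -> sandwich(G)` has no fixed
point for a non-negligible fraction of samples (the exponential bias factors
amplify `G` without bound), while the two-step scheme is stable everywhere
on the simulation grid and reproduces the published operating
characteristics of both corrections. `max_iter`/`tol` expose the full
iteration; divergence returns the last finite iterate flagged `diverged`.

**AR(1)-implied autocovariance.** Only the lag-1 autocorrelation is plugged
into `Omega_II`; higher lags follow the AR(1) structure on the alpha-scale:
`gamma_w(h) = sigma2_w * alpha_to_w_rho(rho_alpha_1^h, sigma2_alpha)` with
`rho_alpha_1` the (inverse-transformed) selected lag-1 value. `L` is chosen
automatically as the first lag where this curve falls below `1e-6` of
`gamma_w(0)`, capped at `min(n - 1, 200)`.

**UB vs MSRC.** The classical unbiased correction (UB) takes the lag-1
moment estimate at face value. Its slight downward bias at high
autocorrelation (rho_alpha >= 0.6) translates into understated standard
errors and inflated type I error. The maximum significant rho correction
(MSRC) screens lags 1..5 with a one-sided Z test at level 0.01
(`Z = rho_hat(h) / sqrt(V_hat)`, alternative: positive autocorrelation),
converts each significant lag-h estimate to an order-1 equivalent by taking
the h-th root on the alpha-scale (where the AR(1) recursion is geometric),
and uses the **maximum** candidate. Selection can only increase the plugged
autocorrelation, so MSRC standard errors are at least as large as UB's
whenever the selected value dominates — conservative by construction. When
no lag is significant (short series), MSRC falls back to the lag-1 estimate
and coincides with UB exactly. Ties in the maximum go to the lowest lag.

Design choices where the convention was genuinely open, each exposed as an
argument: the Z statistic divides by the standard deviation `sqrt(V_hat)`
(a variance in the denominator would be dimensionally wrong;
`denominator="variance"` available); the root transform works on the
alpha-scale (`scale="w"` roots the w-scale value directly); the test is
one-sided for positive autocorrelation (`alternative="two-sided"`
available).

## Numerical safeguards

- `sigma2_w` floored at 1e-8 (flagged); a floored estimate means no
  detectable latent noise and the sandwich degenerates to `Omega_I^{-1}`
  exactly.
- `rho_w(h)` clamped to (-0.999, 0.999). The exact inverse transform of a
  clamped value can leave (-1, 1) on the alpha-scale; it is re-clamped
  before powering, and even roots of negative values are inadmissible
  candidates (excluded from the maximum).
- Bias-correction exponents `|2 x' G x|` capped at 50; beyond that the pass
  is declared divergent.
- Summary tables report alpha-scale nuisance means by transforming each
  replicate and averaging, truncating negative autocorrelation estimates at
  zero first (small-sample moment estimates stray negative routinely, and an
  untruncated mean is dominated by them).

## Monte Carlo harness

The simulation design is the interrupted time series (ITS)
`x_t = (1, t/n, X_t, X_t (t - t0)/n)` with `t0 = n/2` and `X_t = 1` for
`t > t0` (the change point itself counts as pre-intervention). Time is
scaled to (0, 1] so that O(1) intercept/trend coefficients — the study uses
`beta = (1, 1, 0, 0)` under the null and intervention effects 0.4 (level)
and 1.2 (trend) — keep the expected counts per time point between roughly 2
and 14 at every n, the regime of interest; an unscaled `t` with a unit trend
coefficient would overflow the exponential mean immediately.

Replicate `r` of a cell derives all randomness from `base_seed + r`; within
a replicate the latent path and the Poisson draws use separate
`SeedSequence(seed, spawn_key=(0,))` / `(1,)` streams. Keyed streams (rather
than `seed` and `seed + 1`) ensure that consecutive replicates never reuse a
bit stream for different purposes. Results are therefore independent of
execution order, and the three covariance methods are compared on
byte-identical data within each replicate. The latent AR(1) is initialised
from its stationary law, so the moment formulas hold at every `n` without
burn-in. Replicates whose GLM fit fails are dropped and counted; a cell with
more than 1% failures is flagged (none occur on the default grid).

Problem sizes: the packaged experiments run 2000 replicates per
type-I-error cell, 1000 per power cell and 200 for the ITS coverage study —
large enough that every comparison in the acceptance suite is resolved at
three Monte Carlo standard errors, and a full run completes in a few
minutes on one CPU. The original study used 10 000 replicates; the harness
accepts any `n_reps`.

## ITS pipeline and the synthetic daily-count generator

The application-grade design matrix contains an intercept, `2k` harmonics
of period 365.25 days (k = 2), day-of-week (6 contrasts, Monday reference),
holiday (non-holiday reference; Spring-Festival and other-holiday levels),
precipitation category (none / 0–2.5 / >2.5 mm/h), a natural cubic spline
of daily mean temperature (df = 3), linear time, the intervention
indicator, and the intervention times a df = 5 natural spline of time over
the full study period, with `log(population x vehicles)` as offset. Natural
splines use quantile interior knots with boundary knots at the data range;
df columns exclude the intercept. The time-varying intervention effect is
summarised as the excess risk

    ER(t) = (exp(b_X + b_int' ns(t, 5)) - 1) x 100%,

with delta-method CIs on the log scale from the quadratic form
`(1, ns(t,5)) V (1, ns(t,5))'` over the joint intervention block of the
chosen covariance. Point estimates are identical across naive/UB/MSRC by
construction; only interval widths differ (naive ⊆ UB ⊆ MSRC whenever the
selected autocorrelations are ordered). ER is not evaluated outside the
spline's boundary knots.

Because the motivating surveillance data are not public, the generator
`synthesize_rti_data` emulates their structure: subtropical sinusoidal
temperature with noise, wet-season-dependent precipitation, calendar-true
weekdays, a fixed-date synthetic holiday calendar (a 7-day block starting
Feb 1 standing in for the lunar Spring Festival), exposure growing ~7%/yr,
latent AR(1) noise, and a step intervention effect at 20% of the series
(mirroring the early-intervention layout of the motivating study; the
intervention must precede all but the first interior knot of the time
spline, else the interaction block is collinear with the indicator).
Defaults: sigma2_alpha = 0.3, rho_alpha = 0.6, ER step = -40%, ~20 expected
events/day. What it does *not* emulate: lunar-calendar holiday drift,
weather extremes, reporting artifacts, or exposure measured with error — so
passing recovery tests demonstrate correctness of the estimators under the
assumed model, not robustness to real-data misspecification.

## Known limitations

- Poisson observation law only; negative binomial or zero-inflated counts
  are out of scope.
- The ER *point* estimate `exp(eta_hat) - 1` is right-skewed; at high
  latent noise its mean across replicates sits well above the truth even
  though the median is close and CI coverage is nominal. Summaries of ER
  across replicates should use medians.
- The level-change coefficient carries a small negative finite-sample bias
  (order -0.04 at n = 340 under strong latent noise) inherent to the GLM
  estimating equations under multiplicative latent noise; it is negligible
  relative to the coefficient's sampling SD (~0.5).
- MSRC trades power for type-I control; below n ≈ 340 neither correction
  fully controls size (at n = 20 both are far above nominal), matching the
  method's published operating range.
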