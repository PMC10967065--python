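"""Unbiased-correction (UB) sandwich covariance for Poisson GLM estimates.

Under a latent multiplicative noise process ``w_t = exp(alpha_t)`` the
asymptotic covariance of the GLM estimator is

    G_n = Omega_I^{-1} + Omega_I^{-1} Omega_II Omega_I^{-1},

where ``Omega_II = sum_{h=-L}^{L} sum_t x_t x_{t+h}' mu_t mu_{t+h} gamma_w(h)``
carries the latent autocovariance ``gamma_w``.  The nuisance parameters
``sigma2_w`` and ``rho_w(h)`` are estimated by moment estimators whose bias,
of order the sampling variability of beta_hat, is removed using G_n itself —
e.g. ``mu_t^2`` is estimated unbiasedly by ``mu_hat_t^2 exp(-2 x_t' G x_t)``.
This circularity (the estimators need G, G needs the estimators) is resolved
by a fixed-point iteration started at the naive covariance; the one-pass
plug-in is the G = 0 special case.

The same machinery backs both the classical UB correction (order-1
autocorrelation taken at face value) and the maximum-significant-rho
correction in :mod:`countcorr.msrc`, which differ only in the lag-1
autocorrelation plugged into the AR(1)-implied autocovariance curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

import numpy as np

from .core_model import alpha_to_w_rho, w_to_alpha_rho
from .glm_core import GLMFit, naive_covariance

__all__ = [
    "NuisanceEstimates",
    "CorrectedCovariance",
    "estimate_sigma2_w",
    "estimate_rho_w",
    "rho_variance",
    "build_omega_II",
    "ub_correct",
    "SandwichWorkspace",
]

SIGMA2_W_FLOOR = 1e-8
RHO_CLAMP = 0.999
_EXPONENT_CAP = 50.0


@dataclass
class NuisanceEstimates:
    """Moment estimates of the latent-noise nuisance parameters.

    ``rho_w[h-1]`` holds the lag-h w-scale autocorrelation, h = 1..H_max, and
    ``rho_var`` the corresponding estimator variances used by the Z test.
    """

    sigma2_w: float
    rho_w: np.ndarray
    rho_var: np.ndarray
    H_max: int
    floored: bool = False

    @property
    def sigma2_alpha(self) -> float:
        """alpha-scale variance, ``log(1 + sigma2_w)``."""
        return math.log1p(self.sigma2_w)

    def rho_alpha(self, h: int = 1) -> float:
        """alpha-scale autocorrelation at lag h (admissibility-clamped)."""
        return _safe_w_to_alpha(self.rho_w[h - 1], self.sigma2_alpha)


@dataclass
class CorrectedCovariance:
    """Sandwich covariance G_n and the ingredients that produced it."""

    G: np.ndarray
    omega_II: np.ndarray
    nuisance: NuisanceEstimates
    rho1_used: float
    method: str
    L: int
    n_iter: int
    converged: bool
    oscillated: bool = False
    diverged: bool = False
    selection: object = None  # MSRCResult when method == "MSRC"

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.G))

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "G": self.G.tolist(),
            "omega_II": self.omega_II.tolist(),
            "sigma2_w": self.nuisance.sigma2_w,
            "rho_w": self.nuisance.rho_w.tolist(),
            "rho_var": self.nuisance.rho_var.tolist(),
            "rho1_used": self.rho1_used,
            "L": self.L,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "oscillated": self.oscillated,
        }
        if self.selection is not None:
            out["selection"] = self.selection.to_dict()
        return out


def _quad_forms(x: np.ndarray, G: np.ndarray) -> np.ndarray:
    """q_t = x_t' G x_t for every row."""
    return np.einsum("ij,jk,ik->i", x, G, x)


def _check_exponents(q: np.ndarray) -> None:
    worst = float(np.max(np.abs(2.0 * q))) if q.size else 0.0
    if worst > _EXPONENT_CAP:
        raise FloatingPointError(
            f"bias-correction exponent |2 x'Gx| = {worst:.2f} exceeds {_EXPONENT_CAP}; "
            "the fixed point is diverging"
        )


def estimate_sigma2_w(
    y: np.ndarray, mu_hat: np.ndarray, x: np.ndarray, G: np.ndarray
) -> tuple[float, bool]:
    """Bias-corrected moment estimator of ``sigma2_w``.

    Returns ``(estimate, floored)``; the raw moment ratio can be negative at
    small n (overdispersion below Poisson), in which case it is floored at
    ``SIGMA2_W_FLOOR`` and flagged.  With G = 0 this reduces exactly to the
    classical ``sum{(y - mu)^2 - mu} / sum mu^2``.
    """
    q = _quad_forms(x, G)
    _check_exponents(q)
    resid2 = (y - mu_hat) ** 2
    bias = mu_hat ** 2 * np.exp(-2.0 * q) * (np.exp(2.0 * q) - 2.0 * np.exp(q / 2.0) + 1.0)
    num = float(np.sum(resid2 + bias - mu_hat))
    den = float(np.sum(mu_hat ** 2 * np.exp(-2.0 * q)))
    est = num / den
    if est < SIGMA2_W_FLOOR:
        return SIGMA2_W_FLOOR, True
    return est, False


def estimate_rho_w(
    y: np.ndarray,
    mu_hat: np.ndarray,
    x: np.ndarray,
    G: np.ndarray,
    sigma2_w: float,
    h: int,
) -> float:
    """Bias-corrected moment estimator of the lag-h w-scale autocorrelation.

    Uses the pair weight ``g_{t,h} = exp{-(x_t + x_{t+h})' G (x_t + x_{t+h})/2}``;
    the result is clamped to (-0.999, 0.999).  With G = 0 it reduces to the
    classical cross-moment ratio.
    """
    n = len(y)
    if not 1 <= h <= n - 2:
        raise ValueError(f"lag h must satisfy 1 <= h <= n - 2, got {h}")
    if sigma2_w <= 0:
        raise ValueError("sigma2_w must be > 0")
    q = _quad_forms(x, G)
    _check_exponents(q)
    xs = x[:-h] + x[h:]
    g = np.exp(-_quad_forms(xs, G) / 2.0)
    mu_a, mu_b = mu_hat[:-h], mu_hat[h:]
    cross = (y[:-h] - mu_a) * (y[h:] - mu_b)
    bias = mu_a * mu_b * g * (1.0 - np.exp(q[:-h] / 2.0) - np.exp(q[h:] / 2.0) + 1.0 / g)
    est = float(np.sum(cross + bias)) / (sigma2_w * float(np.sum(mu_a * mu_b * g)))
    return float(np.clip(est, -RHO_CLAMP, RHO_CLAMP))


def rho_variance(mu_hat: np.ndarray, sigma2_w: float, h: int) -> float:
    """Variance of the lag-h autocorrelation estimator under independence.

    ``(sum mu_t mu_{t+h})^{-2} sum mu_t^2 mu_{t+h}^2
    (1 + 1/(mu_t sigma2_w)) (1 + 1/(mu_{t+h} sigma2_w))``; for constant mu
    this is ``(1 + 1/(mu sigma2_w))^2 / (n - h)``.
    """
    if sigma2_w <= 0:
        raise ValueError("sigma2_w must be > 0")
    mu_a, mu_b = mu_hat[:-h], mu_hat[h:]
    s = float(np.sum(mu_a * mu_b))
    terms = mu_a ** 2 * mu_b ** 2 * (1.0 + 1.0 / (mu_a * sigma2_w)) * (1.0 + 1.0 / (mu_b * sigma2_w))
    return float(np.sum(terms)) / s ** 2


def build_omega_II(
    x: np.ndarray,
    mu_hat: np.ndarray,
    gamma_w: Callable[[int], float] | np.ndarray,
    L: int,
) -> np.ndarray:
    """Lag-truncated latent-process contribution to the sandwich.

    ``Omega_II = sum_{h=-L}^{L} sum_t x_t x_{t+h}' mu_t mu_{t+h} gamma_w(|h|)``
    — equal to the full double sum over pairs with ``|s - t| <= L``.
    ``gamma_w`` may be a callable on lags 0..L or an array of length L + 1.
    """
    n = x.shape[0]
    if L > n - 1:
        raise ValueError("L must be <= n - 1")
    gam = np.asarray([gamma_w(h) for h in range(L + 1)]) if callable(gamma_w) else np.asarray(gamma_w, float)
    xm = x * mu_hat[:, None]
    omega = gam[0] * (xm.T @ xm)
    for h in range(1, L + 1):
        if gam[h] == 0.0:
            continue
        m = xm[:-h].T @ xm[h:]
        omega = omega + gam[h] * (m + m.T)
    return omega


class SandwichWorkspace:
    """Per-fit cache of the lag cross-moment matrices M_h = sum_t x_t x_{t+h}' mu_t mu_{t+h}.

    Omega_II is a gamma-weighted sum of these, so caching them makes each
    fixed-point iteration (and the second correction method on the same fit)
    a cheap weighted sum instead of a fresh O(n p^2 L) pass.
    """

    def __init__(self, fit: GLMFit):
        self.fit = fit
        self._xm = fit.x * fit.mu_hat[:, None]
        self._m: list[np.ndarray] = [self._xm.T @ self._xm]
        self.omega_I_inv = naive_covariance(fit)

    def m(self, h: int) -> np.ndarray:
        while len(self._m) <= h:
            k = len(self._m)
            self._m.append(self._xm[:-k].T @ self._xm[k:])
        return self._m[h]

    def omega_II(self, gamma: np.ndarray) -> np.ndarray:
        omega = gamma[0] * self.m(0)
        for h in range(1, len(gamma)):
            if gamma[h] == 0.0:
                continue
            mh = self.m(h)
            omega = omega + gamma[h] * (mh + mh.T)
        return omega


def _safe_w_to_alpha(rho_w: float, sigma2_alpha: float) -> float:
    """w->alpha autocorrelation transform, clamping inadmissibly negative input.

    A clamped-at--0.999 w-scale estimate can fall below the lognormal
    admissibility bound when sigma2_w > 1; map it to the most negative
    admissible value instead of raising inside the fixed point.
    """
    if sigma2_alpha <= 0:
        return float(rho_w)
    lo = (-1.0 + 1e-10) / math.expm1(sigma2_alpha)
    return w_to_alpha_rho(max(rho_w, lo) if lo > -1 else rho_w, sigma2_alpha)


def _implied_gamma(
    sigma2_w: float, rho1_w: float, L_spec: int | Literal["auto"], n: int, L_cap: int = 200
) -> np.ndarray:
    """AR(1)-implied w-scale autocovariances gamma_w(0..L).

    The latent process is AR(1) on the alpha-scale, so the order-1 estimate is
    carried to higher lags as ``rho_alpha(1)^h`` there and mapped back:
    ``gamma_w(h) = sigma2_w * alpha_to_w_rho(rho_alpha^h, sigma2_alpha)``.
    With L = "auto" the curve is truncated where it has decayed below 1e-6 of
    gamma_w(0), capped at min(n - 1, 200).
    """
    s2a = math.log1p(sigma2_w)
    # clamp into the stationary AR(1) range: the inverse transform of a
    # clamped w-scale estimate can land slightly outside (-1, 1)
    rho_a = float(np.clip(_safe_w_to_alpha(rho1_w, s2a), -1 + 1e-9, 1 - 1e-9))
    cap = min(n - 1, L_cap)
    rho_w_curve = [1.0]
    h = 1
    while h <= (cap if L_spec == "auto" else min(L_spec, n - 1)):
        val = alpha_to_w_rho(rho_a ** h, s2a)
        if L_spec == "auto" and abs(val) < 1e-6:
            break
        rho_w_curve.append(val)
        h += 1
    return sigma2_w * np.asarray(rho_w_curve)


def _corrected_covariance(
    fit: GLMFit,
    rho_selector: Callable[[NuisanceEstimates], tuple[float, object]],
    method: str,
    H_max: int = 5,
    L: int | Literal["auto"] = "auto",
    max_iter: int = 2,
    tol: float = 1e-6,
    workspace: Optional[SandwichWorkspace] = None,
) -> CorrectedCovariance:
    """Estimate/correct passes shared by the UB and MSRC corrections.

    Pass k estimates the nuisance parameters with the bias corrections
    evaluated at the current covariance G (starting from the naive one) and
    rebuilds the sandwich.  The default ``max_iter = 2`` is the two-step
    estimator — estimate at the naive covariance, correct, re-estimate at the
    corrected covariance, correct again; larger values continue toward the
    fixed point with early exit at relative tolerance ``tol``.  The exact
    fixed point does not exist for every sample at high autocorrelation (the
    exponential bias factors can amplify G without bound), so divergence —
    a bias-correction exponent beyond the cap — returns the last finite
    iterate flagged ``diverged`` rather than raising.
    """
    ws = workspace if workspace is not None else SandwichWorkspace(fit)
    omega_I_inv = ws.omega_I_inv
    y, mu, x, n = fit.y, fit.mu_hat, fit.x, fit.n
    H_max = min(H_max, n - 2)
    G = omega_I_inv
    prev: list[np.ndarray] = []
    state = None  # (nuis, rho1, selection, omega_II, L_used) of the last completed pass
    n_iter, converged, oscillated, diverged = 0, False, False, False
    for n_iter in range(1, max_iter + 1):
        try:
            s2w, floored = estimate_sigma2_w(y, mu, x, G)
            rho = np.array([estimate_rho_w(y, mu, x, G, s2w, h) for h in range(1, H_max + 1)])
        except FloatingPointError:
            diverged = True
            n_iter -= 1
            break
        var = np.array([rho_variance(mu, s2w, h) for h in range(1, H_max + 1)])
        nuis = NuisanceEstimates(sigma2_w=s2w, rho_w=rho, rho_var=var, H_max=H_max, floored=floored)
        rho1, selection = rho_selector(nuis)
        if floored:
            # no detectable latent noise: the model degenerates to a plain GLM
            omega_II = np.zeros_like(G)
            G_new = omega_I_inv
            L_used = 0
        else:
            gamma = _implied_gamma(s2w, rho1, L, n)
            L_used = len(gamma) - 1
            omega_II = ws.omega_II(gamma)
            G_new = omega_I_inv + omega_I_inv @ omega_II @ omega_I_inv
        state = (nuis, rho1, selection, omega_II, L_used)
        scale = float(np.max(np.abs(G_new))) + 1e-300
        if float(np.max(np.abs(G_new - G))) < tol * scale:
            G = G_new
            converged = True
            break
        if len(prev) >= 2 and float(np.max(np.abs(G_new - prev[-2]))) < tol * scale:
            # period-2 cycle: settle on the cycle average
            G = (G_new + prev[-1]) / 2.0
            oscillated = True
            converged = True
            break
        prev.append(G_new)
        G = G_new
    if state is None:
        raise FloatingPointError(
            "bias-correction exponents exploded at the naive covariance; "
            "the correction is undefined for this fit"
        )
    nuis, rho1, selection, omega_II, L_used = state
    G = (G + G.T) / 2.0
    return CorrectedCovariance(
        G=G,
        omega_II=(omega_II + omega_II.T) / 2.0,
        nuisance=nuis,
        rho1_used=float(rho1),
        method=method,
        L=L_used,
        n_iter=n_iter,
        converged=converged,
        oscillated=oscillated,
        diverged=diverged,
        selection=selection,
    )


def ub_correct(
    fit: GLMFit,
    H_max: int = 5,
    L: int | Literal["auto"] = "auto",
    max_iter: int = 2,
    tol: float = 1e-6,
    workspace: Optional[SandwichWorkspace] = None,
) -> CorrectedCovariance:
    """Classical UB-corrected covariance: lag-1 estimate taken as the truth.

    The order-1 w-scale autocorrelation estimate is plugged into the
    AR(1)-implied autocovariance curve at every estimate/correct pass (two
    passes by default; see :func:`_corrected_covariance`).
    """
    return _corrected_covariance(
        fit,
        rho_selector=lambda nuis: (float(nuis.rho_w[0]), None),
        method="UB",
        H_max=H_max,
        L=L,
        max_iter=max_iter,
        tol=tol,
        workspace=workspace,
    )
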