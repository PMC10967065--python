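"""Poisson log-linear GLM fitting and the naive information matrix.

The point estimates of a Poisson GLM remain consistent and asymptotically
normal when the counts carry latent serial dependence, so fitting itself is
the standard maximum-likelihood problem (delegated to statsmodels' IRLS).
What breaks is the covariance: ``Omega_I^{-1}`` — the inverse of the Fisher
information ``Omega_I = sum_t x_t x_t' mu_hat_t`` — understates the variance
of beta_hat.  This module produces the fit and that naive covariance, which
seed the corrected sandwich estimators in :mod:`countcorr.ub_correction`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .core_model import CountSeries

__all__ = ["GLMFit", "GLMFitError", "fit_poisson_glm", "naive_covariance"]

_SCORE_TOL = 1e-8


class GLMFitError(RuntimeError):
    """Fit failure; carries the last iterate when available."""

    def __init__(self, message: str, last_beta=None):
        super().__init__(message)
        self.last_beta = last_beta


@dataclass
class GLMFit:
    """Converged Poisson fit: coefficients, fitted means, information matrix."""

    beta_hat: np.ndarray
    mu_hat: np.ndarray
    omega_I: np.ndarray
    converged: bool
    n_iter: int
    x: np.ndarray
    y: np.ndarray
    offset: np.ndarray

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.x.shape[1]


def fit_poisson_glm(data: CountSeries, max_iter: int = 100) -> GLMFit:
    """Maximum-likelihood Poisson regression with log link and offset.

    Raises :class:`GLMFitError` for rank-deficient designs, all-zero counts
    (the intercept diverges to -inf) and non-convergence; the score equations
    ``sum_t x_t (y_t - mu_hat_t) = 0`` are verified to tolerance after the fit.
    """
    x, y, offset = data.x, data.y, data.offset
    if np.linalg.matrix_rank(x) < data.p:
        raise GLMFitError("design matrix is rank deficient")
    if not np.any(y > 0):
        raise GLMFitError("all counts are zero: Poisson log-likelihood has no maximizer")
    model = sm.GLM(y, x, family=sm.families.Poisson(), offset=offset)
    try:
        res = model.fit(maxiter=max_iter, tol=1e-10)
    except Exception as exc:  # perfect separation, overflow, ...
        raise GLMFitError(f"IRLS failed: {exc}") from exc
    beta = np.asarray(res.params)
    mu = np.exp(offset + x @ beta)
    score = x.T @ (y - mu)
    # relative to the scale of the information so long series are not penalized
    if np.max(np.abs(score)) > _SCORE_TOL * max(1.0, float(np.sum(mu))):
        raise GLMFitError(
            f"score equations not satisfied (max |score| = {np.max(np.abs(score)):.3g})",
            last_beta=beta,
        )
    omega_I = (x * mu[:, None]).T @ x
    return GLMFit(
        beta_hat=beta,
        mu_hat=mu,
        omega_I=omega_I,
        converged=bool(res.converged),
        n_iter=int(getattr(res, "fit_history", {}).get("iteration", max_iter)),
        x=x,
        y=np.asarray(y, dtype=float),
        offset=offset,
    )


def naive_covariance(fit: GLMFit) -> np.ndarray:
    """``Omega_I^{-1}``: the covariance a standard GLM would report.

    Valid only when the counts are serially independent; under a latent
    autocorrelated process it is the first term of the corrected sandwich.
    """
    try:
        cov = np.linalg.inv(fit.omega_I)
    except np.linalg.LinAlgError as exc:
        cond = [f"x{j + 1}" for j in _collinear_columns(fit.x)]
        raise GLMFitError(f"information matrix singular; collinear columns: {cond}") from exc
    return (cov + cov.T) / 2.0


def _collinear_columns(x: np.ndarray) -> list[int]:
    """Indices of columns involved in the (near-)null space of x."""
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    null = vt[s < s[0] * 1e-10]
    if null.size == 0:
        return []
    return sorted(set(np.flatnonzero(np.any(np.abs(null) > 1e-8, axis=0)).tolist()))
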