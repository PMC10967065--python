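"""Parameter-driven Poisson count time series: types, transforms, simulator.

The data-generating model is a Poisson log-linear regression whose mean is
modulated by an unobserved stationary latent process::

    Y_t | alpha_t, x_t ~ Poisson(exp(offset_t + alpha_t + x_t' beta))

with ``alpha_t`` a stationary Gaussian AR(1) sequence.  For identifiability
the latent mean is tied to its variance, ``mu_alpha = -sigma2_alpha / 2``, so
that ``E[exp(alpha_t)] = 1`` and ``exp(x_t' beta)`` remains the marginal mean
of ``Y_t``.  Serial dependence in the counts is inherited entirely from the
latent process; the multiplicative noise ``w_t = exp(alpha_t)`` has its own
(lognormal-scale) variance and autocorrelation, and all estimation downstream
happens on that *w-scale*.  This module provides the exact mappings between
the two scales, the marginal moments of ``Y_t``, a stationary simulator, and
the interrupted time-series (ITS) design matrix used throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LatentParams",
    "WScaleParams",
    "CountSeries",
    "ITSDesign",
    "alpha_to_w_variance",
    "alpha_to_w_rho",
    "w_to_alpha_rho",
    "simulate_latent_ar1",
    "simulate_counts",
    "marginal_moments",
    "build_its_design",
]

logger = logging.getLogger(__name__)

#: Linear-predictor values beyond this raise instead of silently overflowing.
_EXP_OVERFLOW = 700.0


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for (seed, stream).

    Streams are keyed through ``SeedSequence(seed, spawn_key=(stream,))`` so
    that stream 0 of seed ``s`` and stream 1 of seed ``s - 1`` never share an
    underlying bit stream, which plain integer offsets would not guarantee
    when replicate seeds are consecutive integers.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatentParams:
    """Parameters of the latent Gaussian AR(1) process on the alpha-scale.

    Parameters
    ----------
    sigma2_alpha
        Variance of the latent process, >= 0.  Zero degenerates the model to
        an ordinary Poisson GLM.
    rho_alpha
        Lag-1 autocorrelation, in (-1, 1).  The lag-h autocorrelation is
        ``rho_alpha ** h``.

    The mean is not free: ``mu_alpha = -sigma2_alpha / 2`` enforces
    ``E[exp(alpha_t)] = 1``.
    """

    sigma2_alpha: float
    rho_alpha: float

    def __post_init__(self) -> None:
        if self.sigma2_alpha < 0:
            raise ValueError(f"sigma2_alpha must be >= 0, got {self.sigma2_alpha}")
        if not -1 < self.rho_alpha < 1:
            raise ValueError(f"rho_alpha must lie in (-1, 1), got {self.rho_alpha}")

    @property
    def mu_alpha(self) -> float:
        return -self.sigma2_alpha / 2.0

    def rho(self, h: int) -> float:
        """AR(1) autocorrelation at lag ``h >= 0``."""
        return self.rho_alpha ** h

    def to_w_scale(self) -> "WScaleParams":
        s2 = self.sigma2_alpha
        sigma2_w = alpha_to_w_variance(s2)

        def rho_w_fn(h: int) -> float:
            return alpha_to_w_rho(self.rho(h), s2)

        return WScaleParams(sigma2_w=sigma2_w, rho_w_fn=rho_w_fn)


@dataclass(frozen=True)
class WScaleParams:
    """Moments of the multiplicative noise ``w_t = exp(alpha_t)``."""

    sigma2_w: float
    rho_w_fn: Callable[[int], float]

    def gamma_w(self, h: int) -> float:
        """Autocovariance ``gamma_w(h) = sigma2_w * rho_w(h)``."""
        return self.sigma2_w * self.rho_w_fn(h)


@dataclass
class CountSeries:
    """Observed counts with their design matrix and optional log-exposure.

    ``x`` is n x p with an all-ones first column by convention; ``offset`` is
    the log of exposure (zeros when absent).
    """

    y: np.ndarray
    x: np.ndarray
    offset: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2 or len(self.y) != self.x.shape[0]:
            raise ValueError("x must be an n x p matrix matching len(y)")
        if np.any(self.y < 0) or not np.allclose(self.y, np.round(self.y)):
            raise ValueError("counts must be nonnegative integers")
        self.y = self.y.astype(np.int64)
        if self.offset is None:
            self.offset = np.zeros(len(self.y))
        self.offset = np.asarray(self.offset, dtype=float)
        if len(self.offset) != len(self.y) or not np.all(np.isfinite(self.offset)):
            raise ValueError("offset must be finite and match len(y)")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.x.shape[1]

    def to_csv(self, path) -> None:
        cols = {"y": self.y}
        for j in range(self.p):
            cols[f"x{j + 1}"] = self.x[:, j]
        cols["offset"] = self.offset
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CountSeries":
        df = pd.read_csv(path)
        xcols = sorted((c for c in df.columns if c.startswith("x")), key=lambda c: int(c[1:]))
        if "y" not in df.columns or not xcols:
            raise ValueError("CSV must have columns y, x1..xp (and optional offset)")
        offset = df["offset"].to_numpy() if "offset" in df.columns else None
        return cls(y=df["y"].to_numpy(), x=df[xcols].to_numpy(), offset=offset)


@dataclass(frozen=True)
class ITSDesign:
    """Interrupted time-series design: columns (1, t, X, X*(t - t0)).

    The intervention indicator ``X`` is 0 for t <= t0 and 1 after, so the
    change-point time t0 itself belongs to the pre-intervention segment.
    ``time_scale`` divides the two time columns (t and the interaction), which
    keeps the design well conditioned and the trend coefficients O(1) when t
    runs over hundreds of points.
    """

    n: int
    t0: int
    matrix: np.ndarray = field(repr=False)
    time_scale: float = 1.0

    @property
    def intervention_col(self) -> int:
        return 2

    @property
    def interaction_col(self) -> int:
        return 3


# ---------------------------------------------------------------------------
# alpha-scale <-> w-scale transforms
# ---------------------------------------------------------------------------


def alpha_to_w_variance(sigma2_alpha: float) -> float:
    """Variance of w = exp(alpha): ``sigma2_w = exp(sigma2_alpha) - 1``."""
    if sigma2_alpha < 0:
        raise ValueError(f"sigma2_alpha must be >= 0, got {sigma2_alpha}")
    return math.expm1(sigma2_alpha)


def alpha_to_w_rho(rho_alpha_h: float, sigma2_alpha: float) -> float:
    """w-scale autocorrelation at a lag where the alpha-scale one is known.

    ``rho_w(h) = (exp(rho_alpha(h) * s2) - 1) / (exp(s2) - 1)``; the map fixes
    0 and 1 and is strictly increasing.  At ``sigma2_alpha == 0`` the process
    is degenerate and the limit value ``rho_alpha_h`` is returned.
    """
    if sigma2_alpha < 0:
        raise ValueError("sigma2_alpha must be >= 0")
    if abs(rho_alpha_h) > 1 + 1e-12:
        raise ValueError(f"|rho_alpha(h)| must be <= 1, got {rho_alpha_h}")
    if sigma2_alpha == 0:
        logger.debug("alpha_to_w_rho at sigma2_alpha=0: returning limit value")
        return float(rho_alpha_h)
    return math.expm1(rho_alpha_h * sigma2_alpha) / math.expm1(sigma2_alpha)


def w_to_alpha_rho(rho_w_h: float, sigma2_alpha: float) -> float:
    """Exact inverse of :func:`alpha_to_w_rho`.

    Raises when ``1 + rho_w_h * (exp(s2) - 1) <= 0``, i.e. the supplied
    w-scale autocorrelation is more negative than a lognormal pair can attain.
    """
    if sigma2_alpha < 0:
        raise ValueError("sigma2_alpha must be >= 0")
    if sigma2_alpha == 0:
        return float(rho_w_h)
    arg = 1.0 + rho_w_h * math.expm1(sigma2_alpha)
    if arg <= 0:
        raise ValueError(
            f"rho_w = {rho_w_h} is inadmissible for sigma2_alpha = {sigma2_alpha}"
        )
    return math.log(arg) / sigma2_alpha


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_latent_ar1(
    n: int, params: LatentParams, seed: Optional[int] = None, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Stationary draw of the latent Gaussian AR(1) path of length ``n``.

    The first value is drawn from the stationary law N(mu_alpha, sigma2_alpha)
    rather than burning in, so the path is exactly stationary at every n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = _rng(0 if seed is None else seed, 0)
    s2, rho, mu = params.sigma2_alpha, params.rho_alpha, params.mu_alpha
    if s2 == 0:
        return np.full(n, mu)
    z = rng.standard_normal(n)
    alpha = np.empty(n)
    alpha[0] = mu + math.sqrt(s2) * z[0]
    innov_sd = math.sqrt(s2 * (1.0 - rho * rho))
    for t in range(1, n):
        alpha[t] = mu + rho * (alpha[t - 1] - mu) + innov_sd * z[t]
    return alpha


def simulate_counts(
    x: np.ndarray,
    beta: Sequence[float],
    alpha: np.ndarray,
    offset: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> CountSeries:
    """Draw ``Y_t ~ Poisson(exp(offset_t + alpha_t + x_t' beta))`` given alpha."""
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if x.shape[0] != len(alpha):
        raise ValueError("length of alpha must equal number of rows of x")
    if x.shape[1] != len(beta):
        raise ValueError("length of beta must equal number of columns of x")
    if offset is None:
        offset = np.zeros(x.shape[0])
    eta = offset + alpha + x @ beta
    bad = np.flatnonzero(eta > _EXP_OVERFLOW)
    if bad.size:
        raise OverflowError(
            f"Poisson mean overflows at t={int(bad[0])} (linear predictor {eta[bad[0]]:.1f})"
        )
    if rng is None:
        rng = _rng(0 if seed is None else seed, 1)
    y = rng.poisson(np.exp(eta))
    return CountSeries(y=y, x=x, offset=np.asarray(offset, dtype=float))


def simulate_series(
    design: ITSDesign | np.ndarray,
    beta: Sequence[float],
    params: LatentParams,
    seed: int,
    offset: Optional[np.ndarray] = None,
) -> CountSeries:
    """One replicate: latent path (stream 0) then counts (stream 1)."""
    x = design.matrix if isinstance(design, ITSDesign) else np.asarray(design, float)
    alpha = simulate_latent_ar1(x.shape[0], params, rng=_rng(seed, 0))
    return simulate_counts(x, beta, alpha, offset=offset, rng=_rng(seed, 1))


# ---------------------------------------------------------------------------
# marginal moments and the ITS design
# ---------------------------------------------------------------------------


def marginal_moments(
    x_t: Sequence[float],
    beta: Sequence[float],
    params: LatentParams,
    h: int = 1,
    x_th: Optional[Sequence[float]] = None,
) -> tuple[float, float, float]:
    """Marginal mean, variance and lag-h autocorrelation of the counts.

    mu_t = exp(x_t' beta); Var = mu_t + sigma2_w * mu_t^2;
    rho_Y(h) = rho_w(h) / sqrt{(1 + 1/(sigma2_w mu_t)) (1 + 1/(sigma2_w mu_{t+h}))}.
    """
    w = params.to_w_scale()
    mu_t = math.exp(float(np.dot(x_t, beta)))
    mu_th = mu_t if x_th is None else math.exp(float(np.dot(x_th, beta)))
    var_t = mu_t + w.sigma2_w * mu_t ** 2
    if w.sigma2_w == 0 and h > 0:
        return mu_t, var_t, 0.0
    denom = math.sqrt((1 + 1 / (w.sigma2_w * mu_t)) * (1 + 1 / (w.sigma2_w * mu_th)))
    return mu_t, var_t, w.rho_w_fn(h) / denom


def build_its_design(n: int, t0: Optional[int] = None, time_scale: float = 1.0) -> ITSDesign:
    """ITS design matrix with columns (1, t, X, X*(t - t0)), t = 1..n.

    ``t0`` defaults to n // 2 (equal pre/post segments); X_t = 1 for t > t0.
    """
    if t0 is None:
        t0 = n // 2
    if not 1 <= t0 < n:
        raise ValueError(f"t0 must satisfy 1 <= t0 < n, got t0={t0}, n={n}")
    t = np.arange(1, n + 1, dtype=float)
    x_ind = (t > t0).astype(float)
    mat = np.column_stack([np.ones(n), t / time_scale, x_ind, x_ind * (t - t0) / time_scale])
    return ITSDesign(n=n, t0=t0, matrix=mat, time_scale=time_scale)
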