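"""Baranyi–Roberts primary growth model and per-lineage nonlinear fitting.

The model describes log cell quantity ``y(t)`` (here: natural log of
microcolony area in pixels) as

    y(t) = y0 + mu_max * A(t) - ln(1 + (exp(mu_max * A(t)) - 1) / exp(ymax - y0))

with the adjustment function

    A(t) = t + (1 / mu_max) * ln((exp(-mu_max * t) + q0) / (1 + q0)),

where ``q0 = 1 / (exp(h0) - 1)`` encodes the initial physiological state and
``h0 = lag * mu_max`` is the dimensionless "work to be done" before growth.
The curvature parameter of the full model is fixed at m = 1, the common
DMFit-style default.  Everything is formulated in log-sum-exp terms so the
curve is stable for large ``mu_max * t`` and large ``h0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import least_squares

from .config import FitConfig

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .tracking import GrowthSeries

__all__ = [
    "BaranyiParams",
    "FitResult",
    "baranyi_y",
    "fit_baranyi",
    "lag_from_h0",
]


@dataclass(frozen=True)
class BaranyiParams:
    """Parameters of the growth curve, in ln-pixel / hour units."""

    y0: float
    ymax: float
    mu_max: float
    h0: float

    def __post_init__(self) -> None:
        if not (self.mu_max > 0):
            raise ValueError(f"mu_max must be > 0, got {self.mu_max}")
        if self.h0 < 0:
            raise ValueError(f"h0 must be >= 0, got {self.h0}")
        if self.ymax < self.y0:
            raise ValueError(f"ymax ({self.ymax}) must be >= y0 ({self.y0})")

    @property
    def lag(self) -> float:
        """Lag time in hours: h0 / mu_max."""
        return self.h0 / self.mu_max

    @property
    def q0(self) -> float:
        """Initial physiological state, 1 / (e^h0 - 1); inf when h0 = 0."""
        if self.h0 == 0:
            return math.inf
        return 1.0 / math.expm1(self.h0)


def lag_from_h0(h0: float, mu_max: float) -> float:
    """Lag time (h) implied by the work-to-be-done parameter h0."""
    if mu_max <= 0:
        raise ValueError(f"mu_max must be > 0, got {mu_max}")
    if h0 < 0:
        raise ValueError(f"h0 must be >= 0, got {h0}")
    return h0 / mu_max


def _log_expm1(x: np.ndarray | float) -> np.ndarray | float:
    """log(exp(x) - 1), stable for both small and large x."""
    x = np.asarray(x, dtype=float)
    out = np.where(x > 30.0, x, np.log(np.expm1(np.minimum(x, 30.0))))
    return out


def _baranyi_y(t: np.ndarray, y0: float, ymax: float, mu: float, h0: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if h0 == 0.0:
        a = t.copy()
    else:
        # ln q0 = -log(expm1(h0)); A(t) = t + (logaddexp(-mu t, ln q0) - log(1 + q0)) / mu
        ln_q0 = -_log_expm1(h0)
        a = t + (np.logaddexp(-mu * t, ln_q0) - np.logaddexp(0.0, ln_q0)) / mu
    m = mu * a
    d = ymax - y0
    if d <= 0:
        y = np.full_like(t, y0)
    else:
        # ln(1 + (e^m - 1)/e^d) = logaddexp(log(e^d - 1), m) - d
        y = y0 + m - (np.logaddexp(_log_expm1(d), m) - d)
    # A(0) = 0 exactly; pin the time-zero value against round-off
    return np.where(t == 0.0, y0, y)


def baranyi_y(t, params: BaranyiParams):
    """Evaluate ln(area) at time(s) ``t`` (hours, >= 0).

    Accepts a scalar or array; returns the same shape.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    y = _baranyi_y(t_arr, params.y0, params.ymax, params.mu_max, params.h0)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(y)
    return y


@dataclass
class FitResult:
    """Outcome of fitting one growth series.

    ``fittable`` mirrors the bookkeeping used when some microcolonies cannot
    be described by the model: it is False for short series, non-convergent
    fits, fits with RMSE above the configured cap, and fits whose mu_max is
    indistinguishable from zero.
    """

    params: BaranyiParams | None
    rmse: float
    n_points: int
    converged: bool
    fittable: bool
    se: dict[str, float] = field(default_factory=dict)
    message: str = ""

    @property
    def lag(self) -> float:
        return self.params.lag if self.params is not None else math.nan

    @property
    def mu_max(self) -> float:
        return self.params.mu_max if self.params is not None else math.nan


def _initial_guess(t: np.ndarray, y: np.ndarray, cfg: FitConfig):
    """Deterministic initialization from the data.

    mu from the steepest 3-point sliding-window slope; y0 from the first
    observation; ymax from the maximum + 0.5; h0 from a tangent-intersection
    lag guess times the initial mu.
    """
    slopes = (y[2:] - y[:-2]) / (t[2:] - t[:-2])
    i_star = int(np.argmax(slopes))
    mu0 = float(np.clip(slopes[i_star], 1e-3, cfg.mu_upper * 0.99))
    y0_0 = float(y[0])
    ymax0 = float(np.max(y) + 0.5)
    t_w, y_w = float(t[i_star + 1]), float(y[i_star + 1])
    lam_guess = float(np.clip(t_w - (y_w - y0_0) / mu0, 0.0, t[-1]))
    h0_0 = float(np.clip(lam_guess * mu0, 0.0, cfg.h0_upper * 0.99))
    return np.array([y0_0, ymax0, mu0, h0_0])


def fit_baranyi(series: "GrowthSeries", config: FitConfig | None = None) -> FitResult:
    """Nonlinear least-squares fit of ln(area) against the growth curve.

    The fit is fully deterministic (no random restarts).  Series that are
    too short, flat, non-convergent or noisy beyond the RMSE cap come back
    with ``fittable=False`` rather than raising.
    """
    cfg = config or FitConfig()
    t = np.asarray(series.times, dtype=float)
    y = np.asarray(series.ln_areas, dtype=float)
    n = len(t)
    if n < cfg.min_points or len(np.unique(t)) < 3:
        return FitResult(None, math.nan, n, False, False, message="insufficient data")
    if float(np.ptp(y)) < 1e-9:
        return FitResult(None, 0.0, n, False, False, message="no growth")

    x0 = _initial_guess(t, y, cfg)
    lo = np.array([y[0] - 2.0, max(np.max(y) - 0.5, y[0] - 1.5), 1e-4, 0.0])
    hi = np.array([y[0] + 2.0, np.max(y) + 15.0, cfg.mu_upper, cfg.h0_upper])
    x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)

    def resid(theta):
        return _baranyi_y(t, *theta) - y

    try:
        res = least_squares(
            resid, x0, bounds=(lo, hi), method="trf",
            ftol=1e-13, xtol=1e-13, gtol=1e-13, max_nfev=3000,
        )
    except Exception as exc:  # numerical failure, never fatal
        return FitResult(None, math.nan, n, False, False, message=str(exc))

    y0_hat, ymax_hat, mu_hat, h0_hat = (float(v) for v in res.x)
    rmse = float(np.sqrt(np.mean(res.fun**2)))
    converged = bool(res.success)
    ymax_hat = max(ymax_hat, y0_hat)  # bound interplay can leave a hair below
    params = BaranyiParams(y0_hat, ymax_hat, mu_hat, h0_hat)
    fittable = converged and rmse <= cfg.rmse_cap and mu_hat > cfg.min_mu_fittable

    se = _approximate_se(res.jac, res.fun, n, mu_hat, h0_hat)
    return FitResult(params, rmse, n, converged, fittable, se=se,
                     message="" if fittable else "fit rejected")


def _approximate_se(jac: np.ndarray, resid: np.ndarray, n: int,
                    mu: float, h0: float) -> dict[str, float]:
    """Linearized standard errors; lag SE by the delta method."""
    dof = n - 4
    if dof <= 0:
        return {}
    s2 = float(resid @ resid) / dof
    try:
        cov = np.linalg.inv(jac.T @ jac) * s2
    except np.linalg.LinAlgError:
        return {}
    diag = np.sqrt(np.maximum(np.diag(cov), 0.0))
    se = {"y0": diag[0], "ymax": diag[1], "mu_max": diag[2], "h0": diag[3]}
    # lag = h0 / mu: gradient (d/dh0, d/dmu) = (1/mu, -h0/mu^2)
    g = np.array([1.0 / mu, -h0 / mu**2])
    sub = cov[np.ix_([3, 2], [3, 2])]
    se["lag"] = float(np.sqrt(max(g @ sub @ g, 0.0)))
    return se
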