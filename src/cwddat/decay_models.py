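"""Empirical decay-curve fitting and half-life estimation.

Two standard forms describe CWD mass attenuation M_t as a function of time
t (years):

* single exponential, ``M_t = M_0 * exp(-k t)`` — the classical one-constant
  decay model, with the intercept M_0 either fitted or forced to the known
  initial mass;
* power-exponential, ``M_t = M_0 * (t + 1)**k2 * exp(-k1 t)`` — a
  two-constant form whose power term captures the early colonization lag
  (k2 > 0 delays decay relative to the pure exponential).

Half-life (T50, years to 50% mass loss) is closed-form for the exponential,
``T50 = -ln(0.5) / k``, and found by bracketing + bisection for the
power-exponential form, which has no closed-form root.

Fits minimise untransformed residuals by default (log-linear regression is
available via a flag for comparison); R^2 is reported as the squared
Pearson correlation between observed and fitted values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

logger = logging.getLogger("cwddat")

__all__ = [
    "ExponentialFit",
    "PowerExponentialFit",
    "HalfLife",
    "fit_single_exponential",
    "fit_power_exponential",
    "half_life_exponential",
    "half_life_power_exponential",
    "remaining_fraction",
]


@dataclass(frozen=True)
class ExponentialFit:
    """Single-exponential decay fit M_t = M0 * exp(-k t)."""

    k: float
    M0: float
    intercept_forced: bool
    r_squared: float
    residual_sse: float
    non_decaying: bool = False  # set when the best k is <= 0

    def predict(self, t) -> np.ndarray:
        return self.M0 * np.exp(-self.k * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class PowerExponentialFit:
    """Power-exponential decay fit M_t = M0 * (t+1)**k2 * exp(-k1 t)."""

    k1: float
    k2: float
    M0: float
    r_squared: float
    residual_sse: float

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.M0 * (t + 1.0) ** self.k2 * np.exp(-self.k1 * t)


@dataclass(frozen=True)
class HalfLife:
    """Time (years) to 50% mass loss and how it was obtained."""

    t50_years: float
    method: str  # "closed_form" | "iterative"

    def __post_init__(self) -> None:
        if self.t50_years <= 0:
            raise ValueError("half-life must be positive")
        if self.method not in ("closed_form", "iterative"):
            raise ValueError(f"unknown half-life method {self.method!r}")


def _pearson_r2(observed: np.ndarray, fitted: np.ndarray) -> float:
    if np.ptp(observed) == 0 or np.ptp(fitted) == 0:
        return float("nan")
    r = np.corrcoef(observed, fitted)[0, 1]
    return float(r * r)


def _validate_series(times, masses, min_points: int) -> Tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    m = np.asarray(masses, dtype=float)
    if t.shape != m.shape or t.ndim != 1:
        raise ValueError("times and masses must be 1-D arrays of equal length")
    if len(t) < min_points:
        raise ValueError(f"need at least {min_points} points, got {len(t)}")
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t, m


def fit_single_exponential(
    times: Sequence[float],
    masses: Sequence[float],
    force_intercept: bool = False,
    M0_known: Optional[float] = None,
    log_linear: bool = False,
) -> ExponentialFit:
    """Fit the single-exponential decay model by nonlinear least squares.

    With ``force_intercept`` the intercept is fixed at ``M0_known`` (or the
    mass at the earliest time if not given) and only k is free. Non-decaying
    data returns a fit flagged ``non_decaying`` with a logged warning rather
    than an error.
    """
    t, m = _validate_series(times, masses, 2 if force_intercept else 3)

    if force_intercept:
        m0 = float(M0_known) if M0_known is not None else float(m[0])
        if log_linear:
            # slope-only regression of log(m/m0) on t through the origin
            y = np.log(m / m0)
            k = -float(np.sum(t * y) / np.sum(t * t))
        else:
            def resid(k):
                return m0 * np.exp(-k[0] * t) - m
            guess = max((np.log(m[0]) - np.log(m[-1])) / (t[-1] - t[0]), 1e-6)
            sol = optimize.least_squares(resid, x0=[guess], method="lm")
            k = float(sol.x[0])
        fitted = m0 * np.exp(-k * t)
    else:
        if log_linear:
            slope, intercept = np.polyfit(t, np.log(m), 1)
            k, m0 = -float(slope), float(np.exp(intercept))
        else:
            def resid(x):
                return x[1] * np.exp(-x[0] * t) - m
            guess_k = max((np.log(m[0]) - np.log(m[-1])) / (t[-1] - t[0]), 1e-6)
            sol = optimize.least_squares(resid, x0=[guess_k, float(m[0])], method="lm")
            k, m0 = float(sol.x[0]), float(sol.x[1])
        fitted = m0 * np.exp(-k * t)

    non_decaying = k <= 0
    if non_decaying:
        logger.warning("single-exponential fit found non-decaying data (k = %.4g)", k)
    sse = float(np.sum((m - fitted) ** 2))
    return ExponentialFit(
        k=k, M0=m0, intercept_forced=force_intercept,
        r_squared=_pearson_r2(m, fitted), residual_sse=sse,
        non_decaying=non_decaying,
    )


# deterministic 3x3 multi-start grid for (k1, k2)
_K1_STARTS = (0.05, 0.15, 0.5)
_K2_STARTS = (-0.3, 0.0, 0.3)


def fit_power_exponential(
    times: Sequence[float],
    masses: Sequence[float],
    M0_known: Optional[float] = None,
) -> PowerExponentialFit:
    """Fit the power-exponential model for (k1, k2) with M0 fixed.

    The k1/k2 trade-off creates local minima, so the nonlinear least-squares
    solve is repeated from a deterministic 3x3 start grid and the best
    converged solution is kept.
    """
    t, m = _validate_series(times, masses, 4)
    m0 = float(M0_known) if M0_known is not None else float(m[0])

    def resid(x):
        k1, k2 = x
        return m0 * (t + 1.0) ** k2 * np.exp(-k1 * t) - m

    best = None
    for k1_0 in _K1_STARTS:
        for k2_0 in _K2_STARTS:
            try:
                sol = optimize.least_squares(resid, x0=[k1_0, k2_0], method="lm")
            except Exception:  # singular Jacobian at a bad start
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            sse = float(np.sum(sol.fun**2))
            if best is None or sse < best[0] - 1e-15:
                best = (sse, sol.x)
    if best is None:
        raise RuntimeError(
            "power-exponential fit failed to converge from any of the "
            f"{len(_K1_STARTS) * len(_K2_STARTS)} starts; n = {len(t)}, "
            f"mass range = [{m.min():.4g}, {m.max():.4g}]"
        )
    sse, (k1, k2) = best
    fitted = m0 * (t + 1.0) ** k2 * np.exp(-k1 * t)
    return PowerExponentialFit(
        k1=float(k1), k2=float(k2), M0=m0,
        r_squared=_pearson_r2(m, fitted), residual_sse=sse,
    )


def half_life_exponential(k: float) -> HalfLife:
    """Closed-form half-life of the single-exponential model: -ln(0.5)/k."""
    if k <= 0:
        raise ValueError(f"half-life requires k > 0, got {k}")
    return HalfLife(t50_years=-math.log(0.5) / k, method="closed_form")


def half_life_power_exponential(
    k1: float, k2: float, t_max: float = 500.0, tol: float = 1e-9
) -> HalfLife:
    """Iterative half-life of the power-exponential model.

    Finds the root of ``(t+1)**k2 * exp(-k1 t) - 0.5`` by doubling the
    bracket from t = 1 and bisecting until |f| < ``tol``.
    """
    def f(t: float) -> float:
        return (t + 1.0) ** k2 * math.exp(-k1 * t) - 0.5

    lo, hi = 0.0, 1.0
    while f(hi) > 0.0:
        lo, hi = hi, hi * 2.0
        if hi > t_max:
            raise ValueError(
                f"remaining fraction does not cross 0.5 within (0, {t_max}] years "
                f"for k1 = {k1}, k2 = {k2}"
            )
    while True:
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if (abs(fm) < tol and (hi - lo) < 1e-9) or (hi - lo) < 1e-13:
            return HalfLife(t50_years=mid, method="iterative")
        if fm > 0.0:
            lo = mid
        else:
            hi = mid


def remaining_fraction(fit, t) -> float:
    """Evaluate a fit's remaining mass fraction M_t / M0 at time t (years)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = fit.predict(t) / fit.M0
    if out.ndim == 0:
        return float(out)
    return out
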