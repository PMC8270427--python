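"""Model-performance metrics and rating bands for observed-vs-predicted series.

The four metrics are the ones standard in hydrologic and ecosystem model
evaluation:

* E — Nash-Sutcliffe efficiency, ``1 - SSE / SST`` (range (-inf, 1]);
* PBIAS — percent bias, ``100 * sum(O - P) / sum(O)`` (positive when the
  model underpredicts);
* RMSE — root mean squared error with divisor n;
* RRS — RMSE over the observed standard deviation (sample convention,
  divisor n - 1), also known as RSR.

E maps onto five qualitative rating bands (not applicable / poor / fair /
good / excellent, closed on the left); PBIAS is acceptable within
(-25, 25)% and RRS within [0, 0.7].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "PairedSeries",
    "PerformanceReport",
    "nse",
    "pbias",
    "rmse",
    "rrs",
    "r_squared",
    "rate_performance",
    "build_report",
    "read_paired_csv",
]

#: E rating bands, closed on the left: rating applies for lower <= E < upper.
E_BANDS: Tuple[Tuple[float, float, str], ...] = (
    (-math.inf, 0.0, "not applicable"),
    (0.0, 0.25, "poor"),
    (0.25, 0.50, "fair"),
    (0.50, 0.75, "good"),
    (0.75, math.inf, "excellent"),
)

PBIAS_ACCEPTABLE = (-25.0, 25.0)  # open interval, percent
RRS_ACCEPTABLE = (0.0, 0.7)       # closed interval


@dataclass(frozen=True)
class PairedSeries:
    """Aligned observed and predicted values."""

    observed: np.ndarray
    predicted: np.ndarray
    labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        o = np.asarray(self.observed, dtype=float)
        p = np.asarray(self.predicted, dtype=float)
        if o.shape != p.shape or o.ndim != 1:
            raise ValueError("observed and predicted must be 1-D and equal length")
        if len(o) < 2:
            raise ValueError("need at least 2 paired values")
        if not (np.isfinite(o).all() and np.isfinite(p).all()):
            raise ValueError("paired series must be finite")
        object.__setattr__(self, "observed", o)
        object.__setattr__(self, "predicted", p)

    @property
    def n(self) -> int:
        return len(self.observed)


@dataclass(frozen=True)
class PerformanceReport:
    """All evaluation metrics for one observed/predicted comparison."""

    E: float
    R2: float
    PBIAS: float
    RMSE: float
    SD: float
    RRS: float
    mean_observed: float
    mean_predicted: float
    rating: str
    pbias_acceptable: bool
    rrs_acceptable: bool
    n: int

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def nse(s: PairedSeries) -> float:
    """Nash-Sutcliffe efficiency E = 1 - SSE/SST; 1 is a perfect fit."""
    o, p = s.observed, s.predicted
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed values are all equal; E is undefined")
    return 1.0 - float(np.sum((o - p) ** 2)) / sst


def pbias(s: PairedSeries) -> float:
    """Percent bias, 100 * sum(O - P) / sum(O); positive = underprediction."""
    denom = float(np.sum(s.observed))
    if denom == 0.0:
        raise ValueError("sum of observed values is zero; PBIAS is undefined")
    return 100.0 * float(np.sum(s.observed - s.predicted)) / denom


def rmse(s: PairedSeries) -> float:
    """Root mean squared error with divisor n (population convention)."""
    return float(np.sqrt(np.mean((s.observed - s.predicted) ** 2)))


def rrs(s: PairedSeries) -> float:
    """RMSE over the observed standard deviation (sample convention, n-1)."""
    sd = float(np.std(s.observed, ddof=1))
    if sd == 0.0:
        raise ValueError("observed standard deviation is zero; RRS is undefined")
    return rmse(s) / sd


def r_squared(s: PairedSeries) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    if np.ptp(s.observed) == 0 or np.ptp(s.predicted) == 0:
        raise ValueError("R^2 is undefined for a constant series")
    r = float(np.corrcoef(s.observed, s.predicted)[0, 1])
    return r * r


def rate_performance(E: float, PBIAS: Optional[float] = None,
                     RRS: Optional[float] = None) -> Tuple[str, bool, bool]:
    """Map E onto its qualitative rating band and flag PBIAS/RRS acceptability.

    Returns ``(rating, pbias_acceptable, rrs_acceptable)``; the flags are
    True when the corresponding metric was not supplied.
    """
    if not math.isfinite(E):
        raise ValueError("E must be finite")
    rating = next(r for lo, hi, r in E_BANDS if lo <= E < hi)
    pbias_ok = True if PBIAS is None else PBIAS_ACCEPTABLE[0] < PBIAS < PBIAS_ACCEPTABLE[1]
    rrs_ok = True if RRS is None else RRS_ACCEPTABLE[0] <= RRS <= RRS_ACCEPTABLE[1]
    return rating, pbias_ok, rrs_ok


def build_report(s: PairedSeries) -> PerformanceReport:
    """Compute all metrics, means and the rating for one paired series."""
    e = nse(s)
    pb = pbias(s)
    rm = rmse(s)
    sd = float(np.std(s.observed, ddof=1))
    rr = rm / sd
    rating, pbias_ok, rrs_ok = rate_performance(e, pb, rr)
    return PerformanceReport(
        E=e,
        R2=r_squared(s),
        PBIAS=pb,
        RMSE=rm,
        SD=sd,
        RRS=rr,
        mean_observed=float(np.mean(s.observed)),
        mean_predicted=float(np.mean(s.predicted)),
        rating=rating,
        pbias_acceptable=pbias_ok,
        rrs_acceptable=rrs_ok,
        n=s.n,
    )


def read_paired_csv(path) -> PairedSeries:
    """Read a paired CSV with columns ``id,observed,predicted``."""
    df = pd.read_csv(path)
    missing = [c for c in ("observed", "predicted") if c not in df.columns]
    if missing:
        raise ValueError(f"paired CSV {path} missing columns {missing}")
    labels = df["id"].astype(str).tolist() if "id" in df.columns else None
    return PairedSeries(
        observed=df["observed"].to_numpy(dtype=float),
        predicted=df["predicted"].to_numpy(dtype=float),
        labels=labels,
    )
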