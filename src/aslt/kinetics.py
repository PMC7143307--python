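"""Apparent zero-order rate constants from storage time-series.

Oxidation indices that rise linearly with storage time follow pseudo
zero-order kinetics: the rate constant is the slope of value against
time. Fitting proceeds in three steps:

1. segment selection — only the increasing part of the curve is used
   (indices such as pyropheophytin a plateau at high temperature);
2. ordinary least squares on the retained prefix;
3. advisory diagnostics — a lag-phase flag and a responsiveness label
   (indices such as peroxide value may not change at all in sealed
   bottles and then carry no shelf-life information).

The estimator `ZeroOrderKinetics` is scikit-learn compatible
(``fit(t, y)`` / ``predict(t)``); `fit_zero_order` is the functional
wrapper operating on `IndexMeasurementSeries`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .series import IndexMeasurementSeries

__all__ = [
    "ZeroOrderFit",
    "ZeroOrderKinetics",
    "select_increasing_segment",
    "detect_lag",
    "fit_zero_order",
    "classify_responsiveness",
    "FitPreconditionError",
    "DegenerateDesignError",
]


class FitPreconditionError(ValueError):
    """Series does not satisfy the preconditions of a kinetic fit."""


class DegenerateDesignError(ValueError):
    """All observation times identical: slope is unidentifiable."""


@dataclass(frozen=True)
class ZeroOrderFit:
    """Result of a zero-order (linear) kinetic fit.

    Attributes
    ----------
    k : float
        Apparent zero-order rate constant, index units per day (the slope).
    intercept : float
        Fitted initial value, index units.
    se_k, se_intercept : float
        Standard errors of slope and intercept.
    r2 : float
        Coefficient of determination on the retained segment.
    p_slope : float
        Two-sided p-value for slope != 0 (t distribution, n_used - 2 df).
    n_used : int
        Number of observations in the retained segment.
    truncated_at : int
        Index (exclusive) of the last retained observation; equals the
        series length when no truncation occurred.
    lag_flag : bool
        Advisory lag-phase warning; never alters k.
    index_id, temperature, unit : provenance of the fitted series.
    """

    k: float
    intercept: float
    se_k: float
    se_intercept: float
    r2: float
    p_slope: float
    n_used: int
    truncated_at: int
    lag_flag: bool
    index_id: str = ""
    temperature: float = float("nan")
    unit: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form OLS of y on t: (slope, intercept, r2).

    r2 is defined as 1 for an exact fit (including zero-variance y) and 0
    for a zero-variance y with nonzero residuals.
    """
    tm, ym = t.mean(), y.mean()
    sxx = np.sum((t - tm) ** 2)
    if sxx == 0.0:
        raise DegenerateDesignError("all observation times identical")
    sxy = np.sum((t - tm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * tm
    resid = y - (intercept + slope * t)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    if np.isclose(ss_res, 0.0, atol=1e-300):
        r2 = 1.0
    elif ss_tot == 0.0:
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), max(0.0, min(1.0, r2))


class ZeroOrderKinetics(RegressorMixin, BaseEstimator):
    """Zero-order kinetic regression with increasing-segment selection.

    Fits ``value = intercept + k * time`` by ordinary least squares on
    the longest-scoring increasing prefix of the data (see
    :func:`select_increasing_segment`). Observations must be supplied in
    time order; `IndexMeasurementSeries` guarantees this.

    Parameters
    ----------
    min_points : int, default 4
        Minimum number of observations in the retained segment (>= 3).
    select_segment : bool, default True
        If False, fit the full series without truncation.

    Attributes
    ----------
    k_ : float
        Apparent rate constant (slope), units of y per unit of t.
    intercept_ : float
    se_k_, se_intercept_ : float
    r2_ : float
    p_slope_ : float
    n_used_ : int
    truncated_at_ : int
    lag_flag_ : bool
    """

    def __init__(self, min_points: int = 4, select_segment: bool = True):
        self.min_points = min_points
        self.select_segment = select_segment

    def fit(self, t, y):
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.size != y.size:
            raise ValueError("t and y must have the same length")
        if self.min_points < 3:
            raise ValueError("min_points must be >= 3")
        if t.size < self.min_points:
            raise FitPreconditionError(
                f"need at least {self.min_points} observations, got {t.size}"
            )
        if np.any(np.diff(t) < 0):
            raise ValueError("observation times must be sorted non-decreasing")

        if self.select_segment:
            m = _best_increasing_prefix(t, y, self.min_points)
        else:
            m = t.size
        ts, ys = t[:m], y[:m]
        slope, intercept, r2 = _ols_line(ts, ys)
        n = ts.size
        resid = ys - (intercept + slope * ts)
        dof = n - 2
        sigma2 = float(np.sum(resid**2)) / dof if dof > 0 else 0.0
        sxx = float(np.sum((ts - ts.mean()) ** 2))
        se_k = float(np.sqrt(sigma2 / sxx))
        se_b = float(np.sqrt(sigma2 * (1.0 / n + ts.mean() ** 2 / sxx)))
        if se_k > 0:
            tstat = slope / se_k
            p = 2.0 * stats.t.sf(abs(tstat), dof)
        else:
            p = 1.0 if slope == 0.0 else 0.0

        self.k_ = slope
        self.intercept_ = intercept
        self.se_k_ = se_k
        self.se_intercept_ = se_b
        self.r2_ = r2
        self.p_slope_ = float(p)
        self.n_used_ = int(n)
        self.truncated_at_ = int(m)
        self.lag_flag_ = _lag_flag(ts, ys, slope, intercept)
        return self

    def predict(self, t):
        check_is_fitted(self, "k_")
        t = np.asarray(t, dtype=float)
        return self.intercept_ + self.k_ * t

    def to_record(
        self, index_id: str = "", temperature: float = float("nan"), unit: str = ""
    ) -> ZeroOrderFit:
        check_is_fitted(self, "k_")
        return ZeroOrderFit(
            k=self.k_,
            intercept=self.intercept_,
            se_k=self.se_k_,
            se_intercept=self.se_intercept_,
            r2=self.r2_,
            p_slope=self.p_slope_,
            n_used=self.n_used_,
            truncated_at=self.truncated_at_,
            lag_flag=self.lag_flag_,
            index_id=index_id,
            temperature=temperature,
            unit=unit,
        )


def _best_increasing_prefix(t: np.ndarray, y: np.ndarray, min_points: int) -> int:
    """Prefix length maximizing R2 subject to a positive slope.

    Ties break toward the longest prefix; if no prefix has a positive
    slope the full length is returned (the caller reports the
    non-positive slope unchanged).
    """
    n = t.size
    best_m, best_r2 = None, -np.inf
    for m in range(min_points, n + 1):
        ts = t[:m]
        if np.all(ts == ts[0]):
            continue  # slope unidentifiable on this prefix
        slope, _, r2 = _ols_line(ts, y[:m])
        if slope > 0 and r2 >= best_r2:
            best_m, best_r2 = m, r2
    return n if best_m is None else best_m


def _lag_flag(t: np.ndarray, y: np.ndarray, slope: float, intercept: float) -> bool:
    """Advisory lag-phase test on a fitted segment.

    Flags when the earliest observation sits more than two RMS residuals
    below the fitted line and dropping it improves R2.
    """
    resid = y - (intercept + slope * t)
    rmse = float(np.sqrt(np.mean(resid**2)))
    if rmse <= 0.0 or t.size < 4:
        return False
    if resid[0] >= -2.0 * rmse:
        return False
    _, _, r2_full = _ols_line(t, y)
    try:
        _, _, r2_drop = _ols_line(t[1:], y[1:])
    except DegenerateDesignError:
        return False
    return r2_drop > r2_full


def select_increasing_segment(
    series: IndexMeasurementSeries, min_points: int = 4
) -> int:
    """Length of the increasing prefix to retain for the kinetic fit.

    Searches all prefixes of at least ``min_points`` observations for the
    one whose least-squares line has positive slope and maximal R2,
    breaking ties toward the longest. Returns the full length when no
    prefix rises.
    """
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    if len(series) < min_points:
        raise FitPreconditionError(
            f"series {series.index_id}@{series.temperature}C has "
            f"{len(series)} observations; need {min_points}"
        )
    return _best_increasing_prefix(series.times, series.values, min_points)


def detect_lag(series: IndexMeasurementSeries, fit: ZeroOrderFit) -> bool:
    """Advisory lag-phase flag for a fitted series (never modifies k)."""
    m = fit.truncated_at
    return _lag_flag(series.times[:m], series.values[:m], fit.k, fit.intercept)


def fit_zero_order(
    series: IndexMeasurementSeries,
    min_points: int = 4,
    select_segment: bool = True,
    average_replicates: bool = False,
) -> ZeroOrderFit:
    """Apparent zero-order rate constant of one series by linear regression.

    Parameters
    ----------
    series : IndexMeasurementSeries
    min_points : int
        Minimum observations in the retained increasing segment.
    select_segment : bool
        Restrict the regression to the increasing part of the curve.
    average_replicates : bool
        Collapse replicate observations to per-time means before fitting
        (default keeps them as separate observations).
    """
    if average_replicates:
        series = series.averaged_replicates()
    est = ZeroOrderKinetics(min_points=min_points, select_segment=select_segment)
    est.fit(series.times, series.values)
    return est.to_record(series.index_id, series.temperature, series.unit)


def classify_responsiveness(
    fits: Iterable[ZeroOrderFit], alpha: float = 0.05
) -> Mapping[str, str]:
    """Label each index responsive or non-responsive.

    An index is responsive when its slope at the highest tested
    temperature is positive with ``p_slope < alpha``. The label is
    advisory and never blocks fitting.
    """
    by_index: dict[str, list[ZeroOrderFit]] = {}
    for f in fits:
        by_index.setdefault(f.index_id, []).append(f)
    labels: dict[str, str] = {}
    for idx, group in by_index.items():
        top = max(group, key=lambda f: f.temperature)
        responsive = top.k > 0 and top.p_slope < alpha
        labels[idx] = "responsive" if responsive else "non-responsive"
    return labels
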