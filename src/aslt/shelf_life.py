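"""Shelf-life prediction from fitted Arrhenius models.

For a zero-order index rising from an initial value I0 toward an
acceptability limit I_lim, the shelf-life at temperature T is

    SL(T) = (I_lim - I0) / k(T)

with k(T) the Arrhenius-predicted rate. Whole-day values are reported by
flooring. A "shelf-life plot" — ln(SL) regressed on storage temperature
in degC — provides the field's customary extrapolation tool to
temperatures outside the tested range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .arrhenius import ArrheniusModel, predict_rate

__all__ = [
    "AcceptabilityLimit",
    "ShelfLifePrediction",
    "ShelfLifePlotModel",
    "ShelfLifePlot",
    "NonDegradingError",
    "DEFAULT_LIMITS",
    "predict_shelf_life",
    "fit_shelf_life_plot",
    "predict_from_plot",
    "acceleration_factor",
]


class NonDegradingError(ValueError):
    """Predicted rate <= 0: shelf-life is undefined/infinite at this limit."""


@dataclass(frozen=True)
class AcceptabilityLimit:
    """Initial value and acceptability threshold for one index.

    source records provenance, e.g. the EU/IOC regulatory limit for K270
    or the Australian standard for %PPP.
    """

    index_id: str
    I0: float
    I_lim: float
    source: str = "user"

    def __post_init__(self):
        if self.I_lim == self.I0:
            pass  # degenerate but allowed: SL = 0
        elif self.I_lim < self.I0:
            raise ValueError(
                f"{self.index_id}: upper acceptability limit I_lim={self.I_lim} "
                f"must not lie below the initial value I0={self.I0}"
            )

    @property
    def delta(self) -> float:
        return self.I_lim - self.I0


#: Built-in regulatory/standard limits. I0 entries are the measured
#: initial values of the studied oil where published; %PPP has a
#: published limit but no published initial value (callers must supply
#: I0, e.g. the fitted intercept at the lowest temperature).
DEFAULT_LIMITS: dict[str, AcceptabilityLimit] = {
    "K270": AcceptabilityLimit("K270", I0=0.15, I_lim=0.22, source="EU Reg 2568/91"),
    "PV": AcceptabilityLimit("PV", I0=5.7, I_lim=20.0, source="EU Reg 2568/91"),
    "K232": AcceptabilityLimit("K232", I0=1.81, I_lim=2.50, source="EU Reg 2568/91"),
    "PPP": AcceptabilityLimit("PPP", I0=float("nan"), I_lim=17.0,
                              source="Australian standard"),
}


@dataclass(frozen=True)
class ShelfLifePrediction:
    """Shelf-life at one temperature for one index."""

    index_id: str
    temperature: float
    k_T: float
    SL_days: float
    SL_days_floor: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def _lnk_variance(model: ArrheniusModel, temperature_c: float) -> float:
    """Delta-method variance of ln k(T) from the (ln k_ref, Ea) covariance."""
    x = 1.0 / (temperature_c + 273.15) - 1.0 / model.T_ref
    g = np.array([1.0, -x / model.gas_constant])
    return float(g @ model.covariance @ g)


def predict_shelf_life(
    model: ArrheniusModel,
    limit: AcceptabilityLimit,
    temperature: float,
    ci_method: str = "delta",
    confidence: float = 0.95,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> ShelfLifePrediction:
    """Shelf-life SL = (I_lim - I0) / k(T) at a temperature in degC.

    Confidence bounds come from the delta method on ln SL (default) or a
    seeded parametric bootstrap over (ln k_ref, Ea).

    Raises
    ------
    NonDegradingError
        If the predicted rate is not positive — the index never reaches
        the limit and no finite shelf-life exists.
    """
    if limit.index_id and model.index_id and limit.index_id != model.index_id:
        raise ValueError(
            f"limit is for {limit.index_id!r} but model is for {model.index_id!r}"
        )
    k_T = float(predict_rate(model, float(temperature)))
    if k_T <= 0:
        raise NonDegradingError(
            f"{model.index_id or 'index'}: predicted rate {k_T} at "
            f"{temperature} degC is not positive; shelf-life is unbounded"
        )
    sl = limit.delta / k_T
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    ci_low = ci_high = float("nan")
    var_lnk = _lnk_variance(model, float(temperature))
    if sl > 0 and np.isfinite(var_lnk):
        if ci_method == "delta":
            # ln SL = ln(delta) - ln k  =>  se(ln SL) = se(ln k)
            se = math.sqrt(max(var_lnk, 0.0))
            ci_low = sl * math.exp(-z * se)
            ci_high = sl * math.exp(z * se)
        elif ci_method == "bootstrap":
            rng = np.random.default_rng(seed)
            mean = np.array([math.log(model.k_ref), model.Ea])
            draws = rng.multivariate_normal(mean, model.covariance, size=n_boot)
            x = 1.0 / (float(temperature) + 273.15) - 1.0 / model.T_ref
            ks = np.exp(draws[:, 0] - draws[:, 1] / model.gas_constant * x)
            sls = limit.delta / ks
            lo, hi = (1.0 - confidence) / 2.0, 0.5 + confidence / 2.0
            ci_low = float(np.quantile(sls, lo))
            ci_high = float(np.quantile(sls, hi))
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
    return ShelfLifePrediction(
        index_id=model.index_id,
        temperature=float(temperature),
        k_T=k_T,
        SL_days=float(sl),
        SL_days_floor=int(math.floor(sl)),
        ci_low=ci_low,
        ci_high=ci_high,
    )


@dataclass(frozen=True)
class ShelfLifePlotModel:
    """Regression of ln(shelf-life) on storage temperature.

    slope is per degC (or per 1/K when fitted on inverse absolute
    temperature), intercept in ln(days).
    """

    slope: float
    intercept: float
    r2: float
    on_inverse_T: bool = False
    index_id: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


class ShelfLifePlot(RegressorMixin, BaseEstimator):
    """ln(SL) vs temperature regression (the shelf-life plot).

    ``fit(T, SL)`` with T in degC and SL in days; ``predict(T)`` returns
    days. By default the regressor is temperature in degC, matching the
    customary shelf-life plot; ``on_inverse_T=True`` regresses on 1/T(K)
    for an Arrhenius-consistent variant.
    """

    def __init__(self, on_inverse_T: bool = False):
        self.on_inverse_T = on_inverse_T

    def _regressor(self, Tc: np.ndarray) -> np.ndarray:
        return 1.0 / (Tc + 273.15) if self.on_inverse_T else Tc

    def fit(self, T, sl):
        Tc = np.asarray(T, dtype=float).ravel()
        sl = np.asarray(sl, dtype=float).ravel()
        if Tc.size != sl.size:
            raise ValueError("T and sl must have the same length")
        if np.unique(Tc).size < 3:
            raise ValueError("shelf-life plot needs >= 3 distinct temperatures")
        if np.any(sl <= 0):
            raise ValueError("shelf-life values must be positive to take logs")
        x = self._regressor(Tc)
        y = np.log(sl)
        X = np.column_stack([np.ones_like(x), x])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if np.isclose(ss_res, 0.0, atol=1e-300):
            r2 = 1.0
        else:
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        self.intercept_ = float(coef[0])
        self.slope_ = float(coef[1])
        self.r2_ = float(r2)
        return self

    def predict(self, T):
        check_is_fitted(self, "slope_")
        Tc = np.asarray(T, dtype=float).ravel()
        return np.exp(self.intercept_ + self.slope_ * self._regressor(Tc))

    def to_model(self, index_id: str = "") -> ShelfLifePlotModel:
        check_is_fitted(self, "slope_")
        return ShelfLifePlotModel(
            slope=self.slope_,
            intercept=self.intercept_,
            r2=self.r2_,
            on_inverse_T=self.on_inverse_T,
            index_id=index_id,
        )


def fit_shelf_life_plot(
    predictions: Sequence[ShelfLifePrediction], on_inverse_T: bool = False
) -> ShelfLifePlotModel:
    """Fit the shelf-life plot from >= 3 predictions at distinct temperatures."""
    temps = [p.temperature for p in predictions]
    sls = [p.SL_days for p in predictions]
    index_id = predictions[0].index_id if predictions else ""
    est = ShelfLifePlot(on_inverse_T=on_inverse_T).fit(temps, sls)
    return est.to_model(index_id)


def predict_from_plot(plot: ShelfLifePlotModel, temperature: float) -> float:
    """Shelf-life in days from the fitted shelf-life plot."""
    x = 1.0 / (temperature + 273.15) if plot.on_inverse_T else temperature
    return float(np.exp(plot.intercept + plot.slope * x))


def acceleration_factor(
    model: ArrheniusModel, test_temperature: float, market_temperature: float
) -> float:
    """Rate ratio k(test)/k(market).

    Equals SL(market)/SL(test) for any shared acceptability limit, i.e.
    how many times faster the accelerated test ages the product.
    """
    return float(
        predict_rate(model, test_temperature) / predict_rate(model, market_temperature)
    )
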