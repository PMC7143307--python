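"""Temperature dependence of rate constants via the Arrhenius equation.

The classical form k = k0 * exp(-Ea / (R T)) is fitted in its
reparametrized version

    ln k = ln k_ref - (Ea / R) * (1/T - 1/T_ref)

with the reference temperature T_ref chosen mid-range (here 318.15 K,
i.e. 45 degC for a 25-60 degC storage design), which decorrelates the
two parameters. Two fitting routes are provided:

* two-step — rate constants are estimated per temperature first
  (`aslt.kinetics`), then ln k is regressed on (1/T - 1/T_ref). This is
  the default: it is closed-form, and on the published per-temperature
  rates it reproduces the published activation energies.
* one-step — a single nonlinear least-squares fit of all raw
  observations, sharing (Ea, k_ref) across temperatures with a free
  intercept per temperature.

`ArrheniusRegression` (two-step) and `OneStepArrhenius` are
scikit-learn-style estimators; the `fit_arrhenius_*` functions wrap
them and return the serializable `ArrheniusModel` record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .kinetics import ZeroOrderKinetics
from .series import IndexMeasurementSeries

__all__ = [
    "GAS_CONSTANT",
    "T_REF_DEFAULT",
    "celsius_to_kelvin",
    "ArrheniusModel",
    "RateConstantSet",
    "ArrheniusRegression",
    "OneStepArrhenius",
    "fit_arrhenius_twostep",
    "fit_arrhenius_onestep",
    "compute_k0",
    "predict_rate",
    "InsufficientDesignError",
    "EstimationFailureError",
]

#: Molar gas constant in J/(K mol) as used throughout: 8.31 by default
#: (configurable to 8.314; the choice rescales Ea/k0 reporting only and
#: never affects rate or shelf-life predictions).
GAS_CONSTANT = 8.31

#: Default reference temperature: 45 degC, the centre of a 25-60 degC
#: accelerated storage design.
T_REF_DEFAULT = 318.15

ABS_ZERO_C = -273.15


def celsius_to_kelvin(temperature_c) -> np.ndarray | float:
    return np.asarray(temperature_c, dtype=float) + 273.15


class InsufficientDesignError(ValueError):
    """Fewer than two distinct temperatures: Ea is unidentifiable."""


class EstimationFailureError(RuntimeError):
    """Nonlinear estimation failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class RateConstantSet:
    """Per-temperature rate constants for one index.

    entries: sequence of (temperature degC, k in index-units/day, se_k).
    """

    index_id: str
    entries: tuple[tuple[float, float, float], ...]
    unit: str = ""

    def __post_init__(self):
        entries = tuple(
            (float(t), float(k), float(se)) for t, k, se in self.entries
        )
        object.__setattr__(self, "entries", entries)
        temps = {t for t, _, _ in entries}
        if len(temps) < 2:
            raise InsufficientDesignError(
                f"{self.index_id}: need rate constants at >= 2 distinct "
                f"temperatures, got {sorted(temps)}"
            )
        for t, k, _ in entries:
            if not np.isfinite(k):
                raise ValueError(f"{self.index_id}: non-finite k at {t} degC")

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([t for t, _, _ in self.entries])

    @property
    def k(self) -> np.ndarray:
        return np.array([k for _, k, _ in self.entries])

    @property
    def se_k(self) -> np.ndarray:
        return np.array([se for _, _, se in self.entries])


@dataclass
class ArrheniusModel:
    """Fitted temperature dependence of a rate constant.

    Attributes
    ----------
    Ea : float
        Apparent activation energy, J/mol.
    k_ref : float
        Rate at the reference temperature, index units per day.
    T_ref : float
        Reference absolute temperature, K.
    k0 : float
        Pre-exponential factor, exp(ln k_ref + Ea/(R T_ref)).
    gas_constant : float
        R in J/(K mol) used for the fit.
    r2 : float
        Goodness of fit in the fitted space (ln k for log-linear).
    covariance : 2x2 array
        Covariance of (ln k_ref, Ea).
    fit_space : {"log-linear", "nonlinear"}
    method : {"two-step", "one-step"}
    """

    Ea: float
    k_ref: float
    T_ref: float
    gas_constant: float
    r2: float
    covariance: np.ndarray
    fit_space: str
    method: str
    index_id: str = ""
    unit: str = ""
    k0: float = field(init=False)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(2, 2)
        self.k0 = compute_k0(self)

    def predict(self, temperature_c):
        """Rate constant at a temperature in degC."""
        return predict_rate(self, temperature_c)

    def to_dict(self) -> dict:
        return {
            "index": self.index_id,
            "Ea_J_mol": self.Ea,
            "Ea_kJ_mol": self.Ea / 1000.0,
            "k_ref": self.k_ref,
            "T_ref_K": self.T_ref,
            "k0": self.k0,
            "r2": self.r2,
            "fit_space": self.fit_space,
            "method": self.method,
            "gas_constant": self.gas_constant,
            "unit": self.unit,
            "covariance": np.asarray(self.covariance).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArrheniusModel":
        return cls(
            Ea=d["Ea_J_mol"],
            k_ref=d["k_ref"],
            T_ref=d["T_ref_K"],
            gas_constant=d["gas_constant"],
            r2=d["r2"],
            covariance=np.asarray(d["covariance"]),
            fit_space=d["fit_space"],
            method=d["method"],
            index_id=d.get("index", ""),
            unit=d.get("unit", ""),
        )


def compute_k0(model: ArrheniusModel) -> float:
    """Pre-exponential factor k0 = exp(ln k_ref + Ea/(R T_ref))."""
    if model.k_ref <= 0:
        return 0.0  # limiting value; a non-degrading model has no k0
    return float(
        np.exp(np.log(model.k_ref) + model.Ea / (model.gas_constant * model.T_ref))
    )


def predict_rate(model: ArrheniusModel, temperature_c) -> np.ndarray | float:
    """Rate at a temperature in degC from the reparametrized form.

    Identical (algebraically) to k0 * exp(-Ea / (R T)).
    """
    t = np.asarray(temperature_c, dtype=float)
    if np.any(t <= ABS_ZERO_C):
        raise ValueError("temperature at or below absolute zero")
    T = t + 273.15
    x = 1.0 / T - 1.0 / model.T_ref
    out = model.k_ref * np.exp(-model.Ea / model.gas_constant * x)
    return float(out) if np.isscalar(temperature_c) else out


class ArrheniusRegression(RegressorMixin, BaseEstimator):
    """Two-step Arrhenius fit: regress rate constants on temperature.

    ``fit(T, k)`` takes temperatures in degC and the per-temperature rate
    constants. In ``fit_space="log-linear"`` (default) this is closed-form
    OLS of ln k on (1/T - 1/T_ref); ``"nonlinear"`` refines a least-squares
    fit of k itself, initialized from the log-linear solution.

    Parameters
    ----------
    T_ref : float, default 318.15
        Reference absolute temperature in K.
    gas_constant : float, default 8.31
        R in J/(K mol).
    fit_space : {"log-linear", "nonlinear"}

    Attributes
    ----------
    Ea_ : float — apparent activation energy, J/mol.
    k_ref_ : float — rate at T_ref.
    k0_ : float — pre-exponential factor.
    r2_ : float — in the fitted space.
    covariance_ : (2, 2) ndarray — covariance of (ln k_ref, Ea).
    """

    def __init__(
        self,
        T_ref: float = T_REF_DEFAULT,
        gas_constant: float = GAS_CONSTANT,
        fit_space: str = "log-linear",
    ):
        self.T_ref = T_ref
        self.gas_constant = gas_constant
        self.fit_space = fit_space

    def fit(self, T, k):
        if self.T_ref <= 0 or self.gas_constant <= 0:
            raise ValueError("T_ref and gas_constant must be positive")
        if self.fit_space not in ("log-linear", "nonlinear"):
            raise ValueError(f"unknown fit_space {self.fit_space!r}")
        Tc = np.asarray(T, dtype=float).ravel()
        k = np.asarray(k, dtype=float).ravel()
        if Tc.size != k.size:
            raise ValueError("T and k must have the same length")
        if np.unique(Tc).size < 2:
            raise InsufficientDesignError(
                "need rate constants at >= 2 distinct temperatures"
            )
        if self.fit_space == "log-linear" and np.any(k <= 0):
            bad = Tc[k <= 0]
            raise ValueError(
                f"non-positive rate constant at {bad.tolist()} degC cannot be "
                "fitted in log-linear space; use fit_space='nonlinear'"
            )
        x = 1.0 / (Tc + 273.15) - 1.0 / self.T_ref

        lnk = np.log(k) if np.all(k > 0) else None
        if lnk is None and self.fit_space == "nonlinear":
            # crude but safe initialization when logs are unavailable
            theta0 = np.array([np.log(max(k.max(), 1e-12)), 0.0])
            cov0 = np.eye(2)
            r2_lin = 0.0
        else:
            X = np.column_stack([np.ones_like(x), x])
            coef, _, _, _ = np.linalg.lstsq(X, lnk, rcond=None)
            resid = lnk - X @ coef
            dof = max(x.size - 2, 1)
            sigma2 = float(resid @ resid) / dof
            XtX_inv = np.linalg.inv(X.T @ X)
            # params in fit space are (ln k_ref, slope); Ea = -R * slope
            scale = np.diag([1.0, -self.gas_constant])
            cov0 = scale @ (sigma2 * XtX_inv) @ scale.T
            ss_tot = float(np.sum((lnk - lnk.mean()) ** 2))
            ss_res = float(resid @ resid)
            if np.isclose(ss_res, 0.0, atol=1e-300):
                r2_lin = 1.0
            else:
                r2_lin = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
            theta0 = np.array([coef[0], -self.gas_constant * coef[1]])

        if self.fit_space == "log-linear":
            theta, cov, r2 = theta0, cov0, r2_lin
        else:
            theta, cov, r2, _ = _nls_rates(x, k, theta0, self.gas_constant)

        self.Ea_ = float(theta[1])
        self.k_ref_ = float(np.exp(theta[0]))
        self.covariance_ = cov
        self.r2_ = float(r2)
        self.k0_ = float(
            np.exp(theta[0] + self.Ea_ / (self.gas_constant * self.T_ref))
        )
        return self

    def predict(self, T):
        check_is_fitted(self, "Ea_")
        Tc = np.asarray(T, dtype=float).ravel()
        x = 1.0 / (Tc + 273.15) - 1.0 / self.T_ref
        return self.k_ref_ * np.exp(-self.Ea_ / self.gas_constant * x)

    def to_model(self, index_id: str = "", unit: str = "") -> ArrheniusModel:
        check_is_fitted(self, "Ea_")
        return ArrheniusModel(
            Ea=self.Ea_,
            k_ref=self.k_ref_,
            T_ref=self.T_ref,
            gas_constant=self.gas_constant,
            r2=self.r2_,
            covariance=self.covariance_,
            fit_space=self.fit_space,
            method="two-step",
            index_id=index_id,
            unit=unit,
        )


def _nls_rates(x, k, theta0, R, max_nfev=10_000):
    """Least squares of k on exp(ln k_ref - Ea/R * x); theta = (ln k_ref, Ea)."""

    def resid(theta):
        return np.exp(theta[0] - theta[1] / R * x) - k

    sol = least_squares(resid, theta0, method="lm", xtol=1e-10, ftol=1e-10,
                        max_nfev=max_nfev)
    if not sol.success:
        raise EstimationFailureError(
            f"nonlinear Arrhenius fit did not converge: {sol.message}",
            last_iterate=sol.x,
        )
    r = sol.fun
    dof = max(x.size - 2, 1)
    sigma2 = float(r @ r) / dof
    J = sol.jac
    try:
        cov = sigma2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    ss_tot = float(np.sum((k - k.mean()) ** 2))
    ss_res = float(r @ r)
    r2 = 1.0 if np.isclose(ss_res, 0.0, atol=1e-300) else (
        1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    )
    return sol.x, cov, r2, sol


class OneStepArrhenius(RegressorMixin, BaseEstimator):
    """Global nonlinear fit of all raw observations across temperatures.

    Model: value(t, T) = I0_T + k_ref * exp(-Ea/R * (1/T - 1/T_ref)) * t
    with (Ea, k_ref) shared and one intercept per temperature (or a
    single shared intercept). ``fit(X, y)`` takes ``X`` with columns
    (time_days, temperature_degC).

    Attributes after fitting: ``Ea_``, ``k_ref_``, ``k0_``,
    ``intercepts_`` (dict temperature -> I0), ``covariance_`` of
    (ln k_ref, Ea), ``r2_`` (data space), ``n_iter_``.
    """

    def __init__(
        self,
        T_ref: float = T_REF_DEFAULT,
        gas_constant: float = GAS_CONSTANT,
        shared_intercept: bool = False,
        max_nfev: int = 10_000,
    ):
        self.T_ref = T_ref
        self.gas_constant = gas_constant
        self.shared_intercept = shared_intercept
        self.max_nfev = max_nfev

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have columns (time_days, temperature_degC)")
        t, Tc = X[:, 0], X[:, 1]
        temps = np.unique(Tc)
        if temps.size < 2:
            raise InsufficientDesignError("need observations at >= 2 temperatures")
        R = self.gas_constant
        x = 1.0 / (Tc + 273.15) - 1.0 / self.T_ref

        # initialize from the two-step route
        slopes, inits = [], []
        for Tv in temps:
            sel = Tc == Tv
            est = ZeroOrderKinetics(min_points=3, select_segment=False)
            est.fit(t[sel], y[sel])
            slopes.append(max(est.k_, 1e-12))
            inits.append(est.intercept_)
        two = ArrheniusRegression(T_ref=self.T_ref, gas_constant=R).fit(
            temps, slopes
        )
        n_int = 1 if self.shared_intercept else temps.size
        theta0 = np.concatenate(
            [
                [np.log(two.k_ref_), two.Ea_],
                [np.mean(inits)] if self.shared_intercept else inits,
            ]
        )
        group = np.searchsorted(temps, Tc)

        def model(theta):
            lnkref, Ea = theta[0], theta[1]
            icepts = theta[2:]
            i0 = icepts[0] if self.shared_intercept else icepts[group]
            return i0 + np.exp(lnkref - Ea / R * x) * t

        def resid(theta):
            return model(theta) - y

        sol = least_squares(
            resid, theta0, method="lm", xtol=1e-10, ftol=1e-10,
            max_nfev=self.max_nfev,
        )
        if not sol.success:
            raise EstimationFailureError(
                f"one-step Arrhenius fit did not converge: {sol.message}",
                last_iterate=sol.x,
            )
        r = sol.fun
        dof = max(y.size - (2 + n_int), 1)
        sigma2 = float(r @ r) / dof
        try:
            cov_full = sigma2 * np.linalg.inv(sol.jac.T @ sol.jac)
            cov = cov_full[:2, :2]
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        ss_res = float(r @ r)
        r2 = 1.0 if np.isclose(ss_res, 0.0, atol=1e-300) else (
            1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        )

        self.Ea_ = float(sol.x[1])
        self.k_ref_ = float(np.exp(sol.x[0]))
        self.k0_ = float(np.exp(sol.x[0] + self.Ea_ / (R * self.T_ref)))
        icepts = sol.x[2:]
        self.intercepts_ = (
            {float(Tv): float(icepts[0]) for Tv in temps}
            if self.shared_intercept
            else {float(Tv): float(icepts[i]) for i, Tv in enumerate(temps)}
        )
        self.covariance_ = cov
        self.r2_ = float(r2)
        self.n_iter_ = int(sol.nfev)
        self._temps = temps
        return self

    def predict(self, X):
        check_is_fitted(self, "Ea_")
        X = np.asarray(X, dtype=float)
        t, Tc = X[:, 0], X[:, 1]
        x = 1.0 / (Tc + 273.15) - 1.0 / self.T_ref
        i0 = np.array([self.intercepts_.get(float(Tv), np.nan) for Tv in Tc])
        return i0 + self.k_ref_ * np.exp(-self.Ea_ / self.gas_constant * x) * t

    def to_model(self, index_id: str = "", unit: str = "") -> ArrheniusModel:
        check_is_fitted(self, "Ea_")
        return ArrheniusModel(
            Ea=self.Ea_,
            k_ref=self.k_ref_,
            T_ref=self.T_ref,
            gas_constant=self.gas_constant,
            r2=self.r2_,
            covariance=self.covariance_,
            fit_space="nonlinear",
            method="one-step",
            index_id=index_id,
            unit=unit,
            diagnostics={"n_iter": self.n_iter_, "intercepts": self.intercepts_},
        )


def fit_arrhenius_twostep(
    rates: RateConstantSet,
    T_ref: float = T_REF_DEFAULT,
    gas_constant: float = GAS_CONSTANT,
    fit_space: str = "log-linear",
) -> ArrheniusModel:
    """Fit the reparametrized Arrhenius equation to per-temperature rates."""
    est = ArrheniusRegression(
        T_ref=T_ref, gas_constant=gas_constant, fit_space=fit_space
    )
    est.fit(rates.temperatures, rates.k)
    return est.to_model(rates.index_id, rates.unit)


def fit_arrhenius_onestep(
    series_by_temperature: Sequence[IndexMeasurementSeries],
    T_ref: float = T_REF_DEFAULT,
    gas_constant: float = GAS_CONSTANT,
    shared_intercept: bool = False,
    truncate: bool = True,
    min_points: int = 4,
) -> ArrheniusModel:
    """One-step global Arrhenius fit over raw measurement series.

    Each series is truncated to its increasing segment first (set
    ``truncate=False`` if the caller already did).
    """
    from .kinetics import select_increasing_segment

    if not series_by_temperature:
        raise InsufficientDesignError("no series supplied")
    index_id = series_by_temperature[0].index_id
    unit = series_by_temperature[0].unit
    rows_t, rows_T, rows_y = [], [], []
    for s in series_by_temperature:
        m = select_increasing_segment(s, min_points) if truncate else len(s)
        rows_t.append(s.times[:m])
        rows_T.append(np.full(m, s.temperature))
        rows_y.append(s.values[:m])
    X = np.column_stack([np.concatenate(rows_t), np.concatenate(rows_T)])
    y = np.concatenate(rows_y)
    est = OneStepArrhenius(
        T_ref=T_ref, gas_constant=gas_constant, shared_intercept=shared_intercept
    )
    est.fit(X, y)
    return est.to_model(index_id, unit)
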