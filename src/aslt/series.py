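"""Measurement-series container for storage experiments.

A series is one quality index (K270, peroxide value, hexanal, ...)
observed over storage time at a single storage temperature. Replicate
bottles measured at the same time point are kept as separate
observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Index identifiers with built-in unit conventions. User-defined ids are
#: accepted anywhere a series is accepted.
KNOWN_INDICES = (
    "PV",
    "K232",
    "K270",
    "CT",
    "HEXANAL",
    "PPP",
    "PHENOLS",
    "TOCOPHEROLS",
)


class SeriesValidationError(ValueError):
    """Raised when a measurement series violates its invariants."""


@dataclass
class IndexMeasurementSeries:
    """One quality index observed over storage time at one temperature.

    Parameters
    ----------
    index_id : str
        Index name, e.g. ``"K270"`` or ``"HEXANAL"``. Free-form ids are
        allowed for user-defined indices.
    temperature : float
        Storage temperature in degrees Celsius.
    times : array-like of float
        Storage time in days, one entry per observation. Sorted
        non-decreasing on construction (values and replicate labels are
        reordered consistently).
    values : array-like of float
        Measured index values in index-specific units (absorbance for
        K270/K232, meq O2/kg for PV, mg/kg for conjugated trienes and
        hexanal, percent for pyropheophytin a).
    unit : str
        Unit label; must be uniform within a series.
    replicate : array-like, optional
        Replicate identifier per observation.
    """

    index_id: str
    temperature: float
    times: np.ndarray
    values: np.ndarray
    unit: str = ""
    replicate: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise SeriesValidationError(
                f"series {self.index_id}@{self.temperature}C: times and values "
                f"must be 1-D arrays of equal length (got {t.shape} vs {v.shape})"
            )
        if not np.all(np.isfinite(t)):
            raise SeriesValidationError(
                f"series {self.index_id}@{self.temperature}C: non-finite times"
            )
        if not np.all(np.isfinite(v)):
            raise SeriesValidationError(
                f"series {self.index_id}@{self.temperature}C: non-finite values"
            )
        if np.any(t < 0):
            raise SeriesValidationError(
                f"series {self.index_id}@{self.temperature}C: negative storage times"
            )
        rep = self.replicate
        if rep is not None:
            rep = np.asarray(rep)
            if rep.shape != t.shape:
                raise SeriesValidationError(
                    f"series {self.index_id}@{self.temperature}C: replicate length "
                    f"{rep.shape} does not match {t.shape}"
                )
        # stable sort so replicate order at tied times is preserved
        order = np.argsort(t, kind="stable")
        self.times = t[order]
        self.values = v[order]
        self.replicate = None if rep is None else rep[order]

    def __len__(self) -> int:
        return self.times.size

    @property
    def is_fittable(self) -> bool:
        """A zero-order fit needs at least three observations."""
        return len(self) >= 3

    def averaged_replicates(self) -> "IndexMeasurementSeries":
        """Collapse replicate observations to their per-time mean."""
        ut, inv = np.unique(self.times, return_inverse=True)
        means = np.zeros_like(ut)
        for i in range(ut.size):
            means[i] = self.values[inv == i].mean()
        return IndexMeasurementSeries(
            index_id=self.index_id,
            temperature=self.temperature,
            times=ut,
            values=means,
            unit=self.unit,
        )
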