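"""Reading and writing measurement tables, rate tables and model files.

The measurement format is a UTF-8 CSV with a header row and columns
``index, temperature_C, time_days, value, unit, replicate`` (replicate
optional); one file may hold many series. Rate tables (for rates-only
analyses) use ``index, temperature_C, k, se_k, unit``. Models and
reports serialize to JSON at full precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .arrhenius import ArrheniusModel, RateConstantSet
from .series import IndexMeasurementSeries

__all__ = [
    "MeasurementParseError",
    "read_measurements",
    "write_measurements",
    "read_rate_table",
    "write_rate_table",
    "write_json",
    "read_arrhenius_models",
    "write_arrhenius_models",
]

MEASUREMENT_COLUMNS = ("index", "temperature_C", "time_days", "value", "unit")


class MeasurementParseError(ValueError):
    """Malformed measurement file; message carries the offending row."""


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        row = int(df.index[bad][0]) + 2  # header is line 1
        raise MeasurementParseError(
            f"{path}: non-numeric value {df.loc[df.index[bad][0], col]!r} "
            f"in column {col!r} at line {row}"
        )
    if out.isna().any():
        row = int(df.index[out.isna()][0]) + 2
        raise MeasurementParseError(
            f"{path}: missing value in column {col!r} at line {row}"
        )
    # reparse via numpy's correctly-rounded strtod so writing repr() and
    # reading back is bit-exact (pandas' fast parser can be off one ulp)
    return pd.Series(
        np.asarray(df[col].to_numpy(), dtype=np.float64), index=df.index
    )


def read_measurements(path) -> list[IndexMeasurementSeries]:
    """Parse a measurement CSV into series grouped by (index, temperature).

    Enforces unit consistency within each series and reports parse
    failures with the file line number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementParseError(f"{path}: missing column(s) {missing}")
    temperature = _numeric(df, "temperature_C", path)
    time_days = _numeric(df, "time_days", path)
    value = _numeric(df, "value", path)

    work = pd.DataFrame(
        {
            "index": df["index"].str.strip(),
            "temperature_C": temperature,
            "time_days": time_days,
            "value": value,
            "unit": df["unit"].fillna("").str.strip(),
            "replicate": df["replicate"] if "replicate" in df.columns else None,
        }
    )
    series: list[IndexMeasurementSeries] = []
    for (idx, temp), grp in work.groupby(["index", "temperature_C"], sort=True):
        units = grp["unit"].unique()
        if len(units) > 1:
            raise MeasurementParseError(
                f"{path}: series {idx}@{temp}C mixes units {sorted(units)}"
            )
        rep = None
        if "replicate" in df.columns:
            rep = grp["replicate"].to_numpy()
        series.append(
            IndexMeasurementSeries(
                index_id=str(idx),
                temperature=float(temp),
                times=grp["time_days"].to_numpy(float),
                values=grp["value"].to_numpy(float),
                unit=str(units[0]),
                replicate=rep,
            )
        )
    return series


def write_measurements(path, series: Iterable[IndexMeasurementSeries]) -> None:
    """Write series to the measurement CSV format (full precision)."""
    rows = []
    for s in series:
        rep = s.replicate if s.replicate is not None else [""] * len(s)
        for t, v, r in zip(s.times, s.values, rep):
            rows.append(
                {
                    "index": s.index_id,
                    "temperature_C": repr(float(s.temperature)),
                    "time_days": repr(float(t)),
                    "value": repr(float(v)),
                    "unit": s.unit,
                    "replicate": r,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rate_table(path) -> list[RateConstantSet]:
    """Parse a per-temperature rate-constant CSV into RateConstantSets."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for col in ("index", "temperature_C", "k"):
        if col not in df.columns:
            raise MeasurementParseError(f"{path}: missing column {col!r}")
    temp = _numeric(df, "temperature_C", path)
    k = _numeric(df, "k", path)
    if "se_k" in df.columns:
        se = pd.to_numeric(df["se_k"], errors="coerce").fillna(0.0)
    else:
        se = pd.Series(np.zeros(len(df)))
    unit = df["unit"].fillna("") if "unit" in df.columns else pd.Series([""] * len(df))
    work = pd.DataFrame(
        {"index": df["index"].str.strip(), "t": temp, "k": k, "se": se, "unit": unit}
    )
    out = []
    for idx, grp in work.groupby("index", sort=True):
        entries = tuple(
            (float(r.t), float(r.k), float(r.se)) for r in grp.itertuples()
        )
        out.append(
            RateConstantSet(index_id=str(idx), entries=entries,
                            unit=str(grp["unit"].iloc[0]))
        )
    return out


def write_rate_table(path, fits_or_sets) -> None:
    """Write rate constants (ZeroOrderFit records or RateConstantSets) to CSV."""
    rows = []
    for item in fits_or_sets:
        if isinstance(item, RateConstantSet):
            for t, k, se in item.entries:
                rows.append(
                    {"index": item.index_id, "temperature_C": t, "k": repr(k),
                     "se_k": repr(se), "unit": item.unit}
                )
        else:  # ZeroOrderFit
            rows.append(
                {
                    "index": item.index_id,
                    "temperature_C": item.temperature,
                    "k": repr(item.k),
                    "se_k": repr(item.se_k),
                    "unit": item.unit,
                    "intercept": repr(item.intercept),
                    "r2": repr(item.r2),
                    "p_slope": repr(item.p_slope),
                    "n_used": item.n_used,
                    "truncated_at": item.truncated_at,
                    "lag_flag": item.lag_flag,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder) + "\n")


def write_arrhenius_models(path, models: Sequence[ArrheniusModel]) -> None:
    write_json(path, [m.to_dict() for m in models])


def read_arrhenius_models(path) -> list[ArrheniusModel]:
    data = json.loads(Path(path).read_text())
    return [ArrheniusModel.from_dict(d) for d in data]
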