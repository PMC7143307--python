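"""End-to-end analysis pipeline: rates -> Arrhenius -> shelf-life.

`run_pipeline` executes the full chain on measurement files (or, in
rates-only mode, on a published-style rate table), writes per-stage
tables (rates CSV, Arrhenius JSON, shelf-life CSV, shelf-life-plot
JSON) and returns the assembled report. Outputs are a pure function of
(inputs, config, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .arrhenius import (
    GAS_CONSTANT,
    T_REF_DEFAULT,
    ArrheniusModel,
    RateConstantSet,
    fit_arrhenius_onestep,
    fit_arrhenius_twostep,
)
from .io import (
    read_measurements,
    read_rate_table,
    write_arrhenius_models,
    write_json,
    write_rate_table,
)
from .kinetics import ZeroOrderFit, classify_responsiveness, fit_zero_order
from .series import IndexMeasurementSeries
from .shelf_life import (
    DEFAULT_LIMITS,
    AcceptabilityLimit,
    NonDegradingError,
    fit_shelf_life_plot,
    predict_shelf_life,
)

log = logging.getLogger("aslt")

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

SANITY_RANGE_C = (-20.0, 80.0)
CALIBRATED_RANGE_C = (25.0, 60.0)


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration for the end-to-end shelf-life pipeline.

    Either ``measurement_paths`` (raw time series) or ``rate_table_path``
    (per-temperature rate constants, skipping the kinetics stage) must be
    set. ``limits`` maps index ids to acceptability limits; indices
    without a limit are fitted but excluded from shelf-life prediction.
    """

    measurement_paths: tuple[str, ...] = ()
    rate_table_path: str | None = None
    limits: dict[str, AcceptabilityLimit] = field(
        default_factory=lambda: dict(DEFAULT_LIMITS)
    )
    gas_constant: float = GAS_CONSTANT
    T_ref: float = T_REF_DEFAULT
    method: str = "two-step"  # or "one-step"
    fit_space: str = "log-linear"  # or "nonlinear" (two-step only)
    min_points: int = 4
    alpha: float = 0.05
    average_replicates: bool = False
    ci_method: str = "delta"  # or "bootstrap"
    n_boot: int = 1000
    seed: int = 0
    prediction_temperatures: tuple[float, ...] = (25.0, 40.0, 50.0, 60.0)
    output_dir: str | None = None

    def validate(self) -> list[str]:
        problems = []
        if not self.measurement_paths and self.rate_table_path is None:
            problems.append("no measurement files or rate table configured")
        if self.method not in ("two-step", "one-step"):
            problems.append(f"unknown method {self.method!r}")
        for t in self.prediction_temperatures:
            if not SANITY_RANGE_C[0] <= t <= SANITY_RANGE_C[1]:
                problems.append(
                    f"prediction temperature {t} degC outside sanity range "
                    f"{SANITY_RANGE_C}"
                )
        return problems


def _resolve_limit(
    cfg: PipelineConfig, index_id: str, fits: Sequence[ZeroOrderFit]
) -> AcceptabilityLimit | None:
    lim = cfg.limits.get(index_id)
    if lim is None:
        return None
    if math.isnan(lim.I0):
        # fall back to the fitted initial value at the lowest temperature
        candidates = [f for f in fits if f.index_id == index_id]
        if not candidates:
            return None
        coldest = min(candidates, key=lambda f: f.temperature)
        lim = AcceptabilityLimit(
            index_id=lim.index_id,
            I0=coldest.intercept,
            I_lim=lim.I_lim,
            source=lim.source + " (I0 from fit intercept)",
        )
    return lim


def run_pipeline(
    config: PipelineConfig,
    series: Sequence[IndexMeasurementSeries] | None = None,
    rates: Sequence[RateConstantSet] | None = None,
) -> dict:
    """Run rates -> Arrhenius -> shelf-life and assemble the report.

    ``series``/``rates`` may be passed directly (e.g. from the synthetic
    generator) instead of reading the configured paths.
    """
    problems = config.validate() if series is None and rates is None else []
    if problems:
        raise PipelineError("config: " + "; ".join(problems))

    for t in config.prediction_temperatures:
        if not CALIBRATED_RANGE_C[0] <= t <= CALIBRATED_RANGE_C[1]:
            log.warning(
                "prediction at %s degC lies outside the calibrated %s-%s degC span",
                t, *CALIBRATED_RANGE_C,
            )

    report: dict = {"config": {
        "gas_constant": config.gas_constant,
        "T_ref_K": config.T_ref,
        "method": config.method,
        "fit_space": config.fit_space,
        "min_points": config.min_points,
        "alpha": config.alpha,
        "seed": config.seed,
        "prediction_temperatures": list(config.prediction_temperatures),
    }}

    # stage 1: zero-order rate constants
    fits: list[ZeroOrderFit] = []
    series_by_index: dict[str, list[IndexMeasurementSeries]] = {}
    rate_sets: list[RateConstantSet] = []
    try:
        if rates is not None or config.rate_table_path is not None:
            rate_sets = list(rates) if rates is not None else read_rate_table(
                config.rate_table_path
            )
            report["rates_source"] = "rate-table"
        else:
            if series is None:
                series = []
                for p in config.measurement_paths:
                    series.extend(read_measurements(p))
            for s in series:
                series_by_index.setdefault(s.index_id, []).append(s)
                fits.append(
                    fit_zero_order(
                        s,
                        min_points=config.min_points,
                        average_replicates=config.average_replicates,
                    )
                )
            report["rates_source"] = "fitted"
    except Exception as exc:  # noqa: BLE001 - stage name added for callers
        raise PipelineError(f"fit-rates: {exc}") from exc

    labels: dict[str, str] = {}
    if fits:
        labels = dict(classify_responsiveness(fits, alpha=config.alpha))
        by_index: dict[str, list[ZeroOrderFit]] = {}
        for f in fits:
            by_index.setdefault(f.index_id, []).append(f)
        for idx, group in by_index.items():
            if labels.get(idx) == "responsive":
                entries = tuple(
                    (f.temperature, f.k, f.se_k)
                    for f in sorted(group, key=lambda f: f.temperature)
                )
                rate_sets.append(
                    RateConstantSet(index_id=idx, entries=entries,
                                    unit=group[0].unit)
                )
    report["rate_fits"] = [f.to_dict() for f in fits]
    report["responsiveness"] = labels

    # stage 2: Arrhenius temperature dependence. A single index with an
    # unusable rate set (e.g. a borderline-responsive flat index whose
    # slope is negative at some temperature) is skipped with a warning,
    # never aborting the other indices.
    models: list[ArrheniusModel] = []
    stage2_warnings: list[str] = []
    for rs in rate_sets:
        try:
            if config.method == "one-step" and series_by_index.get(rs.index_id):
                model = fit_arrhenius_onestep(
                    series_by_index[rs.index_id],
                    T_ref=config.T_ref,
                    gas_constant=config.gas_constant,
                    min_points=config.min_points,
                )
            else:
                model = fit_arrhenius_twostep(
                    rs,
                    T_ref=config.T_ref,
                    gas_constant=config.gas_constant,
                    fit_space=config.fit_space,
                )
        except Exception as exc:  # noqa: BLE001
            stage2_warnings.append(
                f"fit-arrhenius: {rs.index_id} skipped: {exc}"
            )
            continue
        models.append(model)
    if rate_sets and not models and not stage2_warnings:
        raise PipelineError("fit-arrhenius: no model could be fitted")
    report["arrhenius"] = [m.to_dict() for m in models]

    # stage 3: shelf-life
    predictions: dict[str, list] = {}
    plots: dict[str, dict] = {}
    warnings: list[str] = list(stage2_warnings)
    try:
        for m in models:
            lim = _resolve_limit(config, m.index_id, fits)
            if lim is None:
                warnings.append(
                    f"{m.index_id}: no acceptability limit; shelf-life skipped"
                )
                continue
            preds = []
            for t in config.prediction_temperatures:
                try:
                    preds.append(
                        predict_shelf_life(
                            m, lim, t,
                            ci_method=config.ci_method,
                            n_boot=config.n_boot,
                            seed=config.seed,
                        )
                    )
                except NonDegradingError as exc:
                    warnings.append(str(exc))
            if preds:
                predictions[m.index_id] = preds
                if len({p.temperature for p in preds}) >= 3 and all(
                    p.SL_days > 0 for p in preds
                ):
                    plots[m.index_id] = fit_shelf_life_plot(preds).to_dict()
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"predict-sl: {exc}") from exc

    if not predictions:
        warnings.append("no responsive index with a limit: no shelf-life computable")
    for w in warnings:
        log.warning("%s", w)

    report["shelf_life"] = {
        idx: [p.to_dict() for p in preds] for idx, preds in predictions.items()
    }
    report["shelf_life_plots"] = plots
    report["warnings"] = warnings

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        if fits:
            write_rate_table(out / "rate_constants.csv", fits)
        elif rate_sets:
            write_rate_table(out / "rate_constants.csv", rate_sets)
        write_arrhenius_models(out / "arrhenius_models.json", models)
        _write_shelf_life_table(out / "shelf_life.csv", predictions)
        write_json(out / "report.json", report)
    return report


def _write_shelf_life_table(path, predictions: dict) -> None:
    import pandas as pd

    rows = []
    for idx, preds in predictions.items():
        for p in preds:
            rows.append(
                {
                    "index": idx,
                    "temperature_C": p.temperature,
                    "k_T": repr(p.k_T),
                    "SL_days": repr(p.SL_days),
                    "SL_days_floor": p.SL_days_floor,
                    "ci_low": repr(p.ci_low),
                    "ci_high": repr(p.ci_high),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
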