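"""Arrhenius and shelf-life plots (matplotlib, non-interactive backend)."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .arrhenius import ArrheniusModel, RateConstantSet, predict_rate
from .shelf_life import ShelfLifePrediction

__all__ = ["arrhenius_plot", "shelf_life_plot"]


def arrhenius_plot(
    models: Sequence[ArrheniusModel],
    rate_sets: Mapping[str, RateConstantSet] | None = None,
    path=None,
):
    """ln k against 1/T with the fitted lines; one panel for all indices."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for m in models:
        T = np.linspace(20.0, 65.0, 50)
        ax.plot(1.0 / (T + 273.15), np.log(predict_rate(m, T)), label=m.index_id)
        if rate_sets and m.index_id in rate_sets:
            rs = rate_sets[m.index_id]
            ax.plot(1.0 / (rs.temperatures + 273.15), np.log(rs.k), "o",
                    color=ax.lines[-1].get_color())
    ax.set_xlabel("1/T (1/K)")
    ax.set_ylabel("ln k")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def shelf_life_plot(
    predictions: Mapping[str, Sequence[ShelfLifePrediction]], path=None
):
    """ln(SL) against storage temperature with per-index regression lines."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for idx, preds in predictions.items():
        temps = np.array([p.temperature for p in preds])
        sls = np.array([p.SL_days for p in preds])
        ok = sls > 0
        ax.plot(temps[ok], np.log(sls[ok]), "o-", label=idx)
    ax.set_xlabel("Storage temperature (degC)")
    ax.set_ylabel("ln SL (days)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
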