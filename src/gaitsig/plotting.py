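"""Signature plots: stride-to-stride scatter with fitted curves and 95% bands.

Figures are always accompanied (optionally) by a plain CSV of the plotted
curve data so rendering can be verified without image comparison.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .kinematics import StrideTable
from .regression import WALKING_RANGE, FittedCurve, VelocityRange

__all__ = ["plot_signature"]

_COLORS = ("black", "tab:orange", "tab:red", "tab:blue", "tab:green")


def plot_signature(
    tables: Mapping[str, StrideTable],
    parameter: str,
    fits: Mapping[str, FittedCurve],
    vrange: VelocityRange = WALKING_RANGE,
    out_path=None,
    curve_data_path=None,
    log_scale: bool = False,
    n_grid: int = 200,
):
    """Scatter one gait parameter vs velocity per group, with fitted curves.

    ``fits`` maps group names (matching ``tables``) to fitted curves; each
    curve is drawn over ``vrange`` with its 95% confidence band.  With
    ``log_scale`` the response values are shown on their natural-log scale
    (matching a log response transform in the fit).  If ``curve_data_path``
    is given, the plotted curve grid is exported as CSV (columns: group, v,
    yhat, lo, hi) for deterministic verification.
    """
    fig, ax = plt.subplots(figsize=(5, 4))
    grid = np.linspace(vrange.lower, vrange.upper, n_grid)
    rows = []
    for i, (name, table) in enumerate(tables.items()):
        color = _COLORS[i % len(_COLORS)]
        mask = vrange.contains(table.data["stride_velocity_cm_s"].to_numpy(float))
        v = table.data.loc[mask, "stride_velocity_cm_s"]
        y = table.data.loc[mask, parameter]
        if log_scale:
            y = np.log(y)
        ax.scatter(v, y, s=8, alpha=0.4, color=color, label=name)
        fit = fits.get(name)
        if fit is not None:
            yhat = fit.predict(grid)
            lo, hi = fit.confidence_band(grid)
            ax.plot(grid, yhat, color=color, lw=1.8)
            ax.plot(grid, lo, color="0.2", lw=0.8)
            ax.plot(grid, hi, color="0.2", lw=0.8)
            for g, m, l, h in zip(grid, yhat, lo, hi):
                rows.append({"group": name, "v": g, "yhat": m, "lo": l, "hi": h})
    ax.set_xlabel("stride velocity (cm/s)")
    ax.set_ylabel(("log " if log_scale else "") + parameter)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if curve_data_path is not None:
        pd.DataFrame(rows).to_csv(curve_data_path, index=False)
    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
        return None
    return fig, ax
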