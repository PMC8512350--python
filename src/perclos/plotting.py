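"""Static result-visualisation exports: per-frame state bars and indicator traces."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .classify import EyeStateSeries
from .indicators import ThresholdConfig, WindowIndicators

__all__ = ["plot_session"]


def plot_session(
    series: EyeStateSeries,
    windows: Sequence[WindowIndicators],
    thresholds: Optional[ThresholdConfig] = None,
    path=None,
):
    """Render the session overview chart.

    Top panel: per-frame combined state bars (open, closed, unclassified
    gaps).  Lower panels: PERCLOS, ECD and FEC per window with their fatigue
    thresholds as dashed lines.  Saves to ``path`` when given, else returns
    the figure.
    """
    if thresholds is None:
        thresholds = ThresholdConfig()
    closed, known = series.closed_mask()
    t = np.arange(len(series)) / series.fps

    fig, axes = plt.subplots(4, 1, figsize=(10, 8), sharex=True)
    ax = axes[0]
    ax.fill_between(t, 0, 1, where=known & ~closed, color="tab:green", step="post", label="open")
    ax.fill_between(t, 0, 1, where=known & closed, color="tab:red", step="post", label="closed")
    if (~known).any():
        ax.fill_between(t, 0, 1, where=~known, color="0.7", step="post", label="unclassified")
    ax.set_ylabel("eye state")
    ax.set_yticks([])
    ax.legend(loc="upper right", ncol=3, fontsize=8)

    wt = np.array([(w.start_frame + w.n_frames / 2) / series.fps for w in windows])
    perclos = np.array([w.perclos for w in windows])
    ecd = np.array([np.nan if w.ecd_ms is None else w.ecd_ms for w in windows])
    fec = np.array([w.fec for w in windows], dtype=float)

    for ax, vals, thr, label in (
        (axes[1], perclos, thresholds.perclos_fatigue, "PERCLOS"),
        (axes[2], ecd, thresholds.ecd_fatigue_ms, "ECD [ms]"),
        (axes[3], fec, float(thresholds.fec_fatigue), "FEC"),
    ):
        ax.plot(wt, vals, marker="o", ms=3, lw=1, color="tab:blue")
        ax.axhline(thr, ls="--", color="tab:red", lw=1, label="fatigue threshold")
        ax.set_ylabel(label)
        ax.legend(loc="upper right", fontsize=8)
    axes[3].set_xlabel("time [s]")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
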