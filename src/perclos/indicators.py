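"""Windowed eye-closure fatigue indicators: PERCLOS, ECD, and FEC.

The classified frame series is tiled into consecutive, non-overlapping windows
(default 30 s; N = 1800 frames at 60 fps).  Within each window, counting only
*qualifying* closures (strictly longer than the blink cutoff):

- PERCLOS = qualifying closed frames / N — the proportion of window time the
  eyes are closed; fatigue is indicated above 0.15.
- ECD = qualifying closed frames / number of qualifying clusters — the mean
  cluster duration; fatigue above 400 ms (24 frames at 60 fps).  Undefined
  (reported missing, not zero) when the window has no qualifying cluster.
- FEC = number of qualifying clusters; fatigue above 5 per 30 s window.

PERCLOS is a time fraction, so events spanning a window boundary contribute
their per-window frame counts; ECD and FEC are event-level statistics, so each
event is assigned wholly to the window containing its start frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import EyeStateSeries
from .events import QUALIFYING, ClosureEvent

__all__ = [
    "ThresholdConfig",
    "WindowIndicators",
    "FatigueFlags",
    "SessionSummary",
    "IndicatorError",
    "window_indicators",
    "fatigue_flags",
    "session_summary",
    "export_indicator_table",
    "read_indicator_table",
]

#: Column order of the exported indicator CSV.
CSV_COLUMNS = [
    "window_index",
    "start_frame",
    "n_frames",
    "closed_frames_qualifying",
    "n_clusters",
    "perclos",
    "ecd_frames",
    "ecd_ms",
    "fec",
    "perclos_fatigue",
    "ecd_fatigue",
    "fec_fatigue",
    "unclassified_frames",
    "complete",
    "low_confidence",
]


class IndicatorError(ValueError):
    """Invalid inputs to the indicator computations."""


@dataclass(frozen=True)
class ThresholdConfig:
    """Window length and fatigue-onset thresholds (all exceeded strictly)."""

    window_s: float = 30.0
    perclos_fatigue: float = 0.15
    ecd_fatigue_ms: float = 400.0
    fec_fatigue: int = 5
    #: fraction of unclassified frames above which a window is low-confidence
    max_unclassified_fraction: float = 0.10

    def __post_init__(self) -> None:
        if min(self.window_s, self.perclos_fatigue, self.ecd_fatigue_ms, self.fec_fatigue) <= 0:
            raise IndicatorError("window length and fatigue thresholds must be positive")


@dataclass(frozen=True)
class FatigueFlags:
    perclos_fatigue: bool
    ecd_fatigue: bool
    fec_fatigue: bool


@dataclass(frozen=True)
class WindowIndicators:
    """PERCLOS/ECD/FEC and fatigue flags for one window."""

    window_index: int
    start_frame: int
    n_frames: int
    closed_frames_qualifying: int
    n_clusters: int
    perclos: float
    ecd_frames: Optional[float]
    ecd_ms: Optional[float]
    fec: int
    perclos_fatigue: bool
    ecd_fatigue: bool
    fec_fatigue: bool
    unclassified_frames: int
    complete: bool
    low_confidence: bool


@dataclass(frozen=True)
class SessionSummary:
    """Arithmetic means of the first and last 10 complete windows.

    ECD means skip windows with no qualifying cluster; the number of windows
    actually entering each ECD mean is reported separately.
    """

    perclos_first10: float
    perclos_last10: float
    ecd_ms_first10: Optional[float]
    ecd_ms_last10: Optional[float]
    fec_first10: float
    fec_last10: float
    windows_used_first: int
    windows_used_last: int
    ecd_windows_used_first: int
    ecd_windows_used_last: int


def fatigue_flags(
    perclos: float,
    ecd_ms: Optional[float],
    fec: int,
    thresholds: ThresholdConfig,
) -> FatigueFlags:
    """Apply the fatigue-onset thresholds (strict inequalities, "above").

    A missing ECD never flags.
    """
    return FatigueFlags(
        perclos_fatigue=perclos > thresholds.perclos_fatigue,
        ecd_fatigue=ecd_ms is not None and ecd_ms > thresholds.ecd_fatigue_ms,
        fec_fatigue=fec > thresholds.fec_fatigue,
    )


def window_indicators(
    series: EyeStateSeries,
    events: Sequence[ClosureEvent],
    thresholds: Optional[ThresholdConfig] = None,
) -> list[WindowIndicators]:
    """Compute per-window indicators from a series and its labeled events.

    Windows are half-open frame ranges ``[k*N, (k+1)*N)`` with
    ``N = round(window_s * fps)``.  A trailing partial window is reported with
    its true frame count and ``complete=False``.  Windows with more than the
    configured fraction of unclassified frames are flagged low-confidence.
    """
    if thresholds is None:
        thresholds = ThresholdConfig()
    if any(e.label is None for e in events):
        raise IndicatorError("events must be labeled before computing indicators")
    n_total = len(series)
    N = int(round(thresholds.window_s * series.fps))
    if N < 1:
        raise IndicatorError("window shorter than one frame")
    if n_total == 0:
        raise IndicatorError("empty series")
    n_windows = math.ceil(n_total / N)

    qualifying = [e for e in events if e.label == QUALIFYING]
    closed_in = np.zeros(n_windows, dtype=int)   # PERCLOS numerator, frame-split
    clusters_in = np.zeros(n_windows, dtype=int)  # FEC, start-frame assignment
    cluster_frames_in = np.zeros(n_windows, dtype=int)  # ECD numerator
    for e in qualifying:
        w0 = e.start_frame // N
        w1 = (e.end_frame - 1) // N
        for w in range(w0, w1 + 1):
            lo = max(e.start_frame, w * N)
            hi = min(e.end_frame, (w + 1) * N)
            closed_in[w] += hi - lo
        clusters_in[w0] += 1
        cluster_frames_in[w0] += e.duration_frames

    _, known = series.closed_mask()
    out: list[WindowIndicators] = []
    for w in range(n_windows):
        start = w * N
        n_frames = min(N, n_total - start)
        unclassified = int((~known[start : start + n_frames]).sum())
        perclos = closed_in[w] / n_frames
        n_clusters = int(clusters_in[w])
        if n_clusters > 0:
            ecd_frames: Optional[float] = cluster_frames_in[w] / n_clusters
            ecd_ms: Optional[float] = ecd_frames * 1000.0 / series.fps
        else:
            ecd_frames = ecd_ms = None
        flags = fatigue_flags(perclos, ecd_ms, n_clusters, thresholds)
        out.append(
            WindowIndicators(
                window_index=w,
                start_frame=start,
                n_frames=n_frames,
                closed_frames_qualifying=int(closed_in[w]),
                n_clusters=n_clusters,
                perclos=perclos,
                ecd_frames=ecd_frames,
                ecd_ms=ecd_ms,
                fec=n_clusters,
                perclos_fatigue=flags.perclos_fatigue,
                ecd_fatigue=flags.ecd_fatigue,
                fec_fatigue=flags.fec_fatigue,
                unclassified_frames=unclassified,
                complete=n_frames == N,
                low_confidence=unclassified > thresholds.max_unclassified_fraction * n_frames,
            )
        )
    return out


def session_summary(windows: Sequence[WindowIndicators]) -> SessionSummary:
    """Mean indicators over the first and last min(10, count) complete windows."""
    complete = [w for w in windows if w.complete]
    if not complete:
        raise IndicatorError("no complete windows in session")
    k = min(10, len(complete))
    first, last = complete[:k], complete[-k:]

    def ecd_mean(ws: Sequence[WindowIndicators]) -> tuple[Optional[float], int]:
        vals = [w.ecd_ms for w in ws if w.ecd_ms is not None]
        return (float(np.mean(vals)) if vals else None, len(vals))

    ecd_f, n_ecd_f = ecd_mean(first)
    ecd_l, n_ecd_l = ecd_mean(last)
    return SessionSummary(
        perclos_first10=float(np.mean([w.perclos for w in first])),
        perclos_last10=float(np.mean([w.perclos for w in last])),
        ecd_ms_first10=ecd_f,
        ecd_ms_last10=ecd_l,
        fec_first10=float(np.mean([w.fec for w in first])),
        fec_last10=float(np.mean([w.fec for w in last])),
        windows_used_first=len(first),
        windows_used_last=len(last),
        ecd_windows_used_first=n_ecd_f,
        ecd_windows_used_last=n_ecd_l,
    )


def windows_to_frame(windows: Sequence[WindowIndicators]) -> pd.DataFrame:
    """Tabulate windows with the documented column order."""
    rows = [{c: getattr(w, c) for c in CSV_COLUMNS} for w in windows]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def export_indicator_table(windows: Sequence[WindowIndicators], path) -> None:
    """Write one CSV row per window (comma, dot decimal, UTF-8, header row).

    Missing ECD values are serialized as empty fields, not zeros.  Numbers are
    written with enough digits to round-trip to better than 1e-9.
    """
    if not windows:
        raise IndicatorError("no windows to export")
    df = windows_to_frame(windows)
    df.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_indicator_table(path) -> pd.DataFrame:
    """Read back an exported indicator CSV (missing ECD becomes NaN)."""
    return pd.read_csv(path, encoding="utf-8")
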