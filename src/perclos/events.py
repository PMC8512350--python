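"""Segmentation of the combined closed-eye signal into closure events.

A closure event (cluster) is a maximal run of consecutive frames in which both
eyes are classified as closed.  Events lasting at most the blink cutoff
(200 ms, i.e. 12 frames at 60 fps) are ordinary blinks; strictly longer events
are *qualifying* closures — the only events that enter the fatigue indicators.
Frames whose combined state is missing terminate runs rather than bridging
them, and the adjacent event fragments are marked truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .classify import EyeStateSeries

__all__ = [
    "BLINK",
    "QUALIFYING",
    "ClosureEvent",
    "SegmentationConfig",
    "segment_events",
    "label_events",
    "segment_and_label",
]

BLINK = "blink"
QUALIFYING = "qualifying"


@dataclass(frozen=True)
class ClosureEvent:
    """A maximal run of combined-closed frames."""

    start_frame: int
    duration_frames: int
    duration_ms: float
    label: Optional[str] = None  # None until label_events runs
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.duration_frames < 1:
            raise ValueError("event duration must be at least one frame")

    @property
    def end_frame(self) -> int:
        """Exclusive end frame."""
        return self.start_frame + self.duration_frames


@dataclass(frozen=True)
class SegmentationConfig:
    """Blink/closure boundary configuration.

    The 200 ms blink cutoff is primary; the frame cutoff is derived from the
    frame rate so non-60-fps recordings rescale correctly.
    """

    blink_max_ms: float = 200.0
    fps: float = 60.0

    def __post_init__(self) -> None:
        if self.blink_max_ms <= 0 or self.fps <= 0:
            raise ValueError("blink_max_ms and fps must be positive")
        if self.blink_max_frames < 1:
            raise ValueError("blink cutoff shorter than one frame")

    @property
    def blink_max_frames(self) -> int:
        """Longest duration, in frames, still counted as an ordinary blink."""
        return int(round(self.blink_max_ms * self.fps / 1000.0))


def segment_events(series: EyeStateSeries) -> list[ClosureEvent]:
    """Extract maximal closed runs from a classified series (unlabeled).

    Unclassified frames split runs; fragments adjacent to such gaps, or
    touching the start/end of the series, are flagged truncated.
    """
    closed, known = series.closed_mask()
    n = len(closed)
    events: list[ClosureEvent] = []
    i = 0
    while i < n:
        if known[i] and closed[i]:
            start = i
            while i < n and known[i] and closed[i]:
                i += 1
            dur = i - start
            left_edge = start == 0 or not known[start - 1]
            right_edge = i == n or not known[i]
            events.append(
                ClosureEvent(
                    start_frame=start,
                    duration_frames=dur,
                    duration_ms=dur * 1000.0 / series.fps,
                    truncated=left_edge or right_edge,
                )
            )
        else:
            i += 1
    return events


def label_events(
    events: Sequence[ClosureEvent], config: SegmentationConfig
) -> list[ClosureEvent]:
    """Label each event as blink (duration <= cutoff) or qualifying (>)."""
    cutoff = config.blink_max_frames
    return [
        replace(e, label=BLINK if e.duration_frames <= cutoff else QUALIFYING)
        for e in events
    ]


def segment_and_label(
    series: EyeStateSeries, config: Optional[SegmentationConfig] = None
) -> list[ClosureEvent]:
    """Segment a series and label the events in one step."""
    if config is None:
        config = SegmentationConfig(fps=series.fps)
    return label_events(segment_events(series), config)
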