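"""Ground-truthed synthetic inputs for the fatigue-indicator pipeline.

Three generators, all explicitly seeded (no global random state):

1. :func:`generate_session` — a per-frame eye-aperture signal in [0, 1] with
   two event classes: short, frequent blinks (truncated-normal durations
   capped at the 200 ms blink cutoff) and rarer, heavy-tailed drowsy closures
   (shifted-lognormal durations, always above the cutoff).  An optional linear
   within-session drift ramps the closure rate and closure durations up from
   session start to end, emulating fatigue building over a drive.
2. :func:`render_frames` — renders an aperture signal as a monochrome image
   sequence showing two elliptical eyes whose vertical opening follows the
   aperture, plus Gaussian pixel noise, together with an exact landmark
   provider for the rendered eye centres.  Stands in for camera input.
3. :func:`generate_fss_dataset` — a three-level subjective-fatigue (FSS-S raw
   score) dataset: measurement occasions nested in rested/drowsy condition
   sessions nested in subjects, with random intercepts at the subject and
   condition-within-subject levels.

The default rested/drowsy profiles were calibrated analytically (event rate ×
mean duration) so mean session PERCLOS lands near values reported for real
rested (~0.04–0.07) and drowsy (~0.08–0.15) drivers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import ConfigurationError
from .events import BLINK, SegmentationConfig
from .indicators import ThresholdConfig, WindowIndicators, fatigue_flags

__all__ = [
    "DrowsinessProfile",
    "GroundTruthEvent",
    "GroundTruth",
    "FssSimConfig",
    "GeneratorError",
    "RESTED_PROFILE",
    "DROWSY_PROFILE",
    "CLOSURE_APERTURE",
    "generate_session",
    "render_frames",
    "default_calibration_selections",
    "expected_indicators",
    "generate_fss_dataset",
]

#: Aperture threshold below which the eyes count as closed (the partial-closure
#: convention: an eye covered beyond ~75% of full opening is "closed").
CLOSURE_APERTURE = 0.25


class GeneratorError(RuntimeError):
    """The requested event process could not be realised (e.g. overlap rejection)."""


@dataclass(frozen=True)
class DrowsinessProfile:
    """Generative parameters for a synthetic eye-closure session.

    Parameters
    ----------
    blink_rate : events per minute.
    blink_dur_ms : (mean, sd) of a truncated normal, capped at 200 ms.
    closure_rate : drowsy-closure events per minute (session-start rate).
    closure_dur_ms : (log-mean, log-sd) of a lognormal *added to* 200 ms, so
        every closure outlasts the blink cutoff.
    drift : linear multiplier ramp on closure rate and closure duration;
        both scale by ``1 + drift * t/T`` across the session.
    seed : default seed used when :func:`generate_session` gets none.
    """

    blink_rate: float = 15.0
    blink_dur_ms: tuple[float, float] = (110.0, 30.0)
    closure_rate: float = 6.0
    closure_dur_ms: tuple[float, float] = (5.3, 0.5)
    drift: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blink_rate < 0 or self.closure_rate < 0:
            raise ValueError("event rates must be non-negative")
        if self.blink_dur_ms[0] <= 0 or self.blink_dur_ms[1] < 0:
            raise ValueError("blink duration parameters invalid")
        if self.drift < 0:
            raise ValueError("drift must be non-negative")


#: A rested driver: sparse short closures, mean session PERCLOS ~ 0.05.
RESTED_PROFILE = DrowsinessProfile(
    blink_rate=15.0, blink_dur_ms=(110.0, 30.0),
    closure_rate=6.0, closure_dur_ms=(5.3, 0.5), drift=0.3,
)

#: A drowsy driver: more and longer closures, mean session PERCLOS ~ 0.13.
DROWSY_PROFILE = DrowsinessProfile(
    blink_rate=12.0, blink_dur_ms=(120.0, 40.0),
    closure_rate=9.0, closure_dur_ms=(5.7, 0.6), drift=0.5,
)


@dataclass(frozen=True)
class GroundTruthEvent:
    start_frame: int
    duration_frames: int
    kind: str  # "blink" or "closure"

    @property
    def end_frame(self) -> int:
        return self.start_frame + self.duration_frames


@dataclass(frozen=True)
class GroundTruth:
    """The true event placement underlying a synthetic session."""

    events: tuple[GroundTruthEvent, ...]
    fps: float
    total_frames: int

    def __post_init__(self) -> None:
        prev_end = -1
        for e in self.events:
            if e.start_frame <= prev_end:
                raise ValueError("ground-truth events must be disjoint and sorted")
            prev_end = e.end_frame - 1

    def closed_mask(self) -> np.ndarray:
        mask = np.zeros(self.total_frames, dtype=bool)
        for e in self.events:
            mask[e.start_frame : e.end_frame] = True
        return mask

    def qualifying_events(self, blink_max_frames: int) -> list[GroundTruthEvent]:
        return [e for e in self.events if e.duration_frames > blink_max_frames]


def _duration_frames(dur_ms: float, fps: float) -> int:
    # ceil keeps shifted-lognormal closures strictly above the blink cutoff
    # after frame quantisation, at any fps.
    return max(1, math.ceil(dur_ms * fps / 1000.0))


def _ramp_positions(rng: np.random.Generator, n: int, drift: float) -> np.ndarray:
    """Sample n event times in [0, 1) with density proportional to 1 + drift*t."""
    u = rng.random(n)
    if drift == 0:
        return u
    # inverse CDF of f(t) = (1 + drift t) / (1 + drift/2)
    return (np.sqrt(1.0 + u * (2.0 * drift + drift**2)) - 1.0) / drift


def generate_session(
    profile: DrowsinessProfile,
    duration_s: float,
    fps: float = 60.0,
    seed: Optional[int] = None,
    max_retries: int = 1000,
) -> tuple[np.ndarray, GroundTruth]:
    """Simulate one session's eye-aperture signal with ground truth.

    Returns ``(aperture, ground_truth)`` where ``aperture`` holds one value in
    [0, 1] per frame.  Frames inside events dip below :data:`CLOSURE_APERTURE`
    and all other frames stay above it, so thresholding the aperture recovers
    the ground-truth closed mask exactly.  Event counts are Poisson with the
    profile rates (closure rate modulated by the drift ramp); events never
    overlap (rejection sampling with bounded retries).
    """
    if seed is None:
        seed = profile.seed
    rng = np.random.default_rng(seed)
    total_frames = int(round(duration_s * fps))
    seg = SegmentationConfig(fps=fps)
    if total_frames < 1:
        raise ValueError("session must contain at least one frame")
    minutes = duration_s / 60.0

    # event counts
    n_closures = rng.poisson(profile.closure_rate * minutes * (1.0 + profile.drift / 2.0))
    n_blinks = rng.poisson(profile.blink_rate * minutes)

    proposals: list[tuple[float, int, str]] = []  # (position in [0,1), frames, kind)
    mu, sigma = profile.closure_dur_ms
    for pos in _ramp_positions(rng, n_closures, profile.drift):
        dur_ms = (seg.blink_max_ms + rng.lognormal(mu, sigma)) * (1.0 + profile.drift * pos)
        proposals.append((pos, _duration_frames(dur_ms, fps), "closure"))
    bmean, bsd = profile.blink_dur_ms
    for pos in rng.random(n_blinks):
        dur_ms = float(np.clip(rng.normal(bmean, bsd), 30.0, seg.blink_max_ms))
        proposals.append((pos, _duration_frames(dur_ms, fps), BLINK))

    occupied = np.zeros(total_frames, dtype=bool)
    placed: list[GroundTruthEvent] = []
    for pos, dur, kind in proposals:
        dur = min(dur, total_frames)
        start = int(pos * (total_frames - dur + 1))
        tries = 0
        while occupied[start : start + dur].any():
            tries += 1
            if tries > max_retries:
                raise GeneratorError(
                    "could not place non-overlapping events; rates too high "
                    "for the session length"
                )
            start = int(rng.integers(0, total_frames - dur + 1))
        occupied[start : start + dur] = True
        placed.append(GroundTruthEvent(start, dur, "closure" if kind == "closure" else BLINK))
    placed.sort(key=lambda e: e.start_frame)

    aperture = rng.uniform(0.9, 1.0, total_frames)
    for e in placed:
        aperture[e.start_frame : e.end_frame] = rng.uniform(0.02, 0.2, e.duration_frames)
    gt = GroundTruth(events=tuple(placed), fps=fps, total_frames=total_frames)
    return aperture, gt


# ---------------------------------------------------------------------------
# frame rendering

_EYE_SEMI_AXES = (10.0, 6.0)  # horizontal, max vertical, pixels
_MIN_VERTICAL = 0.8           # residual lid line when fully closed
DEFAULT_PATCH = 28            # template patch edge, pixels


class RenderedEyeCenters:
    """Exact landmark provider for rendered frames (centres are known)."""

    def __init__(self, left: tuple[float, float], right: tuple[float, float]):
        self.left = left
        self.right = right

    def __call__(self, frame_index, frame=None):
        return self.left, self.right


def render_frames(
    aperture: Sequence[float],
    image_size: tuple[int, int] = (64, 96),
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, RenderedEyeCenters]:
    """Render an aperture signal as a monochrome eye-region sequence.

    Each frame shows two dark elliptical eyes on a bright background; the
    vertical semi-axis scales with the frame's aperture, with a residual lid
    line when fully closed.  Independent Gaussian pixel noise with standard
    deviation ``noise_sd`` (intensity units, frames live in [0, 1]) is added.
    Returns the frame stack ``(n, h, w) float32`` and a perfect landmark
    provider for the rendered centres.
    """
    aperture = np.asarray(aperture, dtype=np.float64)
    if aperture.ndim != 1:
        raise ValueError("aperture must be a 1-D sequence")
    if np.any((aperture < 0) | (aperture > 1)):
        raise ValueError("aperture values must lie in [0, 1]")
    h, w = image_size
    a, b_max = _EYE_SEMI_AXES
    margin = DEFAULT_PATCH // 2 + 2
    cy = h / 2.0
    cxl, cxr = w / 3.0, 2.0 * w / 3.0
    if h < 2 * margin or cxr - cxl < 2 * a or cxl < margin or w - cxr < margin:
        raise ConfigurationError(f"image size {image_size} too small for the eye geometry")

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    rng = np.random.default_rng(seed)
    frames = np.empty((len(aperture), h, w), dtype=np.float32)
    background, iris = 0.85, 0.15
    for i, ap in enumerate(aperture):
        b = max(_MIN_VERTICAL, b_max * ap)
        img = np.full((h, w), background)
        for cx in (cxl, cxr):
            inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
            img[inside] = iris
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        frames[i] = np.clip(img, 0.0, 1.0)
    return frames, RenderedEyeCenters(left=(cxl, cy), right=(cxr, cy))


def default_calibration_selections(
    aperture: Sequence[float],
    image_size: tuple[int, int] = (64, 96),
    n_pairs: int = 3,
    patch: int = DEFAULT_PATCH,
) -> list[tuple[int, tuple[int, int, int, int], tuple[int, int, int, int]]]:
    """Pick open-eye frames and eye regions suitable for template calibration.

    Selects ``n_pairs`` frames with near-full aperture, spread across the
    session, and returns ``(frame, left_region, right_region)`` selections in
    the (x, y, width, height) convention used by :func:`~perclos.classify.build_templates`.
    """
    aperture = np.asarray(aperture, dtype=np.float64)
    open_frames = np.flatnonzero(aperture >= 0.9)
    if len(open_frames) < n_pairs:
        raise GeneratorError("not enough open frames to calibrate from")
    picks = open_frames[np.linspace(0, len(open_frames) - 1, n_pairs).astype(int)]
    h, w = image_size
    cy = h / 2.0
    regions = []
    for cx in (w / 3.0, 2.0 * w / 3.0):
        x0 = int(round(cx)) - patch // 2
        y0 = int(round(cy)) - patch // 2
        regions.append((x0, y0, patch, patch))
    return [(int(f), regions[0], regions[1]) for f in picks]


def expected_indicators(
    gt: GroundTruth,
    thresholds: Optional[ThresholdConfig] = None,
    seg: Optional[SegmentationConfig] = None,
) -> list[WindowIndicators]:
    """Indicators computed directly from ground-truth events.

    Independent of the classification/segmentation pipeline: works straight
    off the event list by window arithmetic, providing the analytic
    counterpart for generator/analyzer closure checks.
    """
    if thresholds is None:
        thresholds = ThresholdConfig()
    if seg is None:
        seg = SegmentationConfig(fps=gt.fps)
    N = int(round(thresholds.window_s * gt.fps))
    n_windows = math.ceil(gt.total_frames / N)
    qualifying = gt.qualifying_events(seg.blink_max_frames)
    out = []
    for wi in range(n_windows):
        lo, hi = wi * N, min((wi + 1) * N, gt.total_frames)
        n_frames = hi - lo
        closed = sum(max(0, min(e.end_frame, hi) - max(e.start_frame, lo)) for e in qualifying)
        starters = [e for e in qualifying if lo <= e.start_frame < hi]
        n_clusters = len(starters)
        ecd_frames = sum(e.duration_frames for e in starters) / n_clusters if starters else None
        ecd_ms = ecd_frames * 1000.0 / gt.fps if ecd_frames is not None else None
        perclos = closed / n_frames
        flags = fatigue_flags(perclos, ecd_ms, n_clusters, thresholds)
        out.append(
            WindowIndicators(
                window_index=wi,
                start_frame=lo,
                n_frames=n_frames,
                closed_frames_qualifying=closed,
                n_clusters=n_clusters,
                perclos=perclos,
                ecd_frames=ecd_frames,
                ecd_ms=ecd_ms,
                fec=n_clusters,
                perclos_fatigue=flags.perclos_fatigue,
                ecd_fatigue=flags.ecd_fatigue,
                fec_fatigue=flags.fec_fatigue,
                unclassified_frames=0,
                complete=n_frames == N,
                low_confidence=False,
            )
        )
    return out


# ---------------------------------------------------------------------------
# three-level subjective-fatigue data

@dataclass(frozen=True)
class FssSimConfig:
    """Data-generating process for three-level FSS-S raw scores.

    ``fss_s = fixed_intercept + fixed_time_slope * occasion
    + fixed_indicator_slope * indicator + u_subject + u_condition + eps``
    with ``u_subject ~ N(0, var_subject)`` per subject, ``u_condition ~
    N(0, var_condition)`` per condition session within subject, and residual
    ``eps ~ N(0, var_residual)`` per occasion.  The active indicator (default
    the mean eye-closure duration, ``ecd``) carries the fixed slope; the other
    two named indicators are null predictors with the same marginal
    distribution.  Default variance components sit near the magnitudes
    estimated for real drivers (roughly 130–350 / 200–470 / 125–180).
    """

    n_subjects: int = 8
    fixed_intercept: float = 25.0
    fixed_time_slope: float = 5.0
    fixed_indicator_slope: float = 10.0
    var_subject: float = 200.0
    var_condition: float = 230.0
    var_residual: float = 170.0
    indicator_mean: float = 0.0
    indicator_sd: float = 1.0
    indicator_condition_shift: float = 1.0
    active_indicator: str = "ecd"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.var_subject, self.var_condition, self.var_residual) < 0:
            raise ValueError("variance components must be non-negative")
        if self.indicator_sd < 0:
            raise ValueError("indicator_sd must be non-negative")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.active_indicator not in ("perclos", "ecd", "fec"):
            raise ValueError("active_indicator must be perclos, ecd, or fec")


def generate_fss_dataset(config: FssSimConfig) -> pd.DataFrame:
    """Simulate a tidy subject x condition x occasion FSS-S table.

    Columns: ``subject``, ``condition`` (rested/drowsy), ``occasion`` (0 =
    pre-test, 1 = post-test), ``perclos``, ``ecd``, ``fec`` (the named
    indicator summaries, the active one driving the response), ``indicator``
    (alias of the active column), and ``fss_s``.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    names = ("perclos", "ecd", "fec")
    for subj in range(config.n_subjects):
        u_subj = rng.normal(0.0, math.sqrt(config.var_subject))
        for cond_idx, cond in enumerate(("rested", "drowsy")):
            u_cond = rng.normal(0.0, math.sqrt(config.var_condition))
            for occ in (0, 1):
                inds = {
                    name: rng.normal(
                        config.indicator_mean + config.indicator_condition_shift * cond_idx,
                        config.indicator_sd,
                    )
                    for name in names
                }
                eps = rng.normal(0.0, math.sqrt(config.var_residual))
                fss = (
                    config.fixed_intercept
                    + config.fixed_time_slope * occ
                    + config.fixed_indicator_slope * inds[config.active_indicator]
                    + u_subj
                    + u_cond
                    + eps
                )
                rows.append(
                    dict(
                        subject=subj,
                        condition=cond,
                        occasion=occ,
                        **inds,
                        indicator=inds[config.active_indicator],
                        fss_s=fss,
                    )
                )
    return pd.DataFrame(rows)
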