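"""Per-frame eye-state classification by normalized-correlation template matching.

A calibration set holds one or more pairs of open-eye template patches (left and
right eye).  Each video frame is classified by extracting a patch around each
eye centre (supplied by a pluggable landmark provider) and matching it against
the templates in sequence: the first template whose normalized correlation
score reaches the acceptance threshold declares the eye *open*; if every
template scores below the threshold the eye is *closed*.  The eyes are treated
as closed only when both eyes are closed.  Frames where the landmark provider
finds no eye centres stay *unclassified* and can later be resolved from an
override file, mirroring a manual-correction workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "OPEN",
    "CLOSED",
    "UNCLASSIFIED",
    "DEFAULT_THRESHOLD",
    "CalibrationError",
    "ClassificationError",
    "ConfigurationError",
    "DegenerateInputError",
    "OverrideError",
    "TemplatePair",
    "CalibrationSet",
    "FrameClassification",
    "EyeStateSeries",
    "LandmarkProvider",
    "build_templates",
    "match_score",
    "classify_frame",
    "classify_sequence",
    "apply_overrides",
    "series_from_mask",
    "extract_patch",
]

OPEN = "open"
CLOSED = "closed"
UNCLASSIFIED = "unclassified"

#: Match-score acceptance cutoff for declaring an eye open.
DEFAULT_THRESHOLD = 0.68


class CalibrationError(ValueError):
    """Invalid template selection or calibration set."""


class ClassificationError(ValueError):
    """Invalid inputs to the frame classifier."""


class ConfigurationError(ValueError):
    """Calibration incompatible with the video geometry."""


class DegenerateInputError(ValueError):
    """A patch or template with zero intensity variance (uninformative)."""


class OverrideError(ValueError):
    """An override range falls outside the series."""


# A landmark provider maps (frame_index, frame) to ((lx, ly), (rx, ry)) pixel
# coordinates of the left/right eye centres, or None when no face was found.
LandmarkProvider = Callable[
    [int, np.ndarray], Optional[tuple[tuple[float, float], tuple[float, float]]]
]


@dataclass(frozen=True)
class TemplatePair:
    """One pair of left/right eye template patches cut from a source frame."""

    left: np.ndarray
    right: np.ndarray
    source_frame: int

    def __post_init__(self) -> None:
        for name, patch in (("left", self.left), ("right", self.right)):
            if patch.ndim != 2 or patch.size == 0:
                raise CalibrationError(f"{name} template must be a non-empty 2-D patch")
            if not np.all(np.isfinite(patch)):
                raise CalibrationError(f"{name} template contains non-finite intensities")
        if self.left.shape != self.right.shape:
            raise CalibrationError(
                f"left/right template shapes differ: {self.left.shape} vs {self.right.shape}"
            )

    @property
    def patch_size(self) -> tuple[int, int]:
        """(height, width) of the template patches in pixels."""
        return self.left.shape


@dataclass(frozen=True)
class CalibrationSet:
    """Ordered template pairs plus the match-score acceptance threshold."""

    pairs: tuple[TemplatePair, ...]
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if len(self.pairs) < 1:
            raise CalibrationError("calibration requires at least one template pair")
        if not (0.0 < self.threshold <= 1.0):
            raise CalibrationError(f"threshold must be in (0, 1], got {self.threshold}")
        size = self.pairs[0].patch_size
        for pair in self.pairs:
            if pair.patch_size != size:
                raise CalibrationError("all template pairs must share one patch size")
            for patch in (pair.left, pair.right):
                if float(np.std(patch)) == 0.0:
                    raise CalibrationError(
                        f"zero-variance template from frame {pair.source_frame}"
                    )

    @property
    def patch_size(self) -> tuple[int, int]:
        return self.pairs[0].patch_size


@dataclass(frozen=True)
class FrameClassification:
    """Eye states and best match scores for a single video frame."""

    frame_index: int
    left_state: str = UNCLASSIFIED
    right_state: str = UNCLASSIFIED
    best_score_left: Optional[float] = None
    best_score_right: Optional[float] = None
    landmark_found: bool = False
    patch_padded: bool = False

    @property
    def combined_closed(self) -> Optional[bool]:
        """True iff both eyes closed; None when either eye is unclassified."""
        if UNCLASSIFIED in (self.left_state, self.right_state):
            return None
        return self.left_state == CLOSED and self.right_state == CLOSED


@dataclass(frozen=True)
class EyeStateSeries:
    """Ordered per-frame classifications for one recording."""

    frames: tuple[FrameClassification, ...]
    fps: float = 60.0
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        for i, fc in enumerate(self.frames):
            if fc.frame_index != i:
                raise ValueError(
                    f"frame indices must run 0..n-1; position {i} holds {fc.frame_index}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return len(self.frames) / self.fps

    def closed_mask(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (closed, known) boolean arrays over frames.

        ``known[i]`` is False where the combined state is missing (an
        unclassified eye); ``closed[i]`` is only meaningful where known.
        """
        closed = np.zeros(len(self.frames), dtype=bool)
        known = np.zeros(len(self.frames), dtype=bool)
        for i, fc in enumerate(self.frames):
            cc = fc.combined_closed
            if cc is not None:
                known[i] = True
                closed[i] = cc
        return closed, known


def match_score(patch: np.ndarray, template: np.ndarray) -> float:
    """Normalized correlation match score in [0, 1].

    The Pearson correlation coefficient of the two patches' intensities,
    clamped below at zero: anti-correlated patches count as "no match".
    Identical patches score 1 (up to numeric tolerance); a higher value means
    a better match.  Symmetric in its arguments.

    Raises
    ------
    DegenerateInputError
        If either patch has zero intensity variance, which would make the
        correlation undefined.
    ClassificationError
        If the shapes differ.
    """
    patch = np.asarray(patch, dtype=np.float64)
    template = np.asarray(template, dtype=np.float64)
    if patch.shape != template.shape:
        raise ClassificationError(
            f"patch shape {patch.shape} does not match template shape {template.shape}"
        )
    a = patch - patch.mean()
    b = template - template.mean()
    denom = float(np.sqrt((a * a).sum() * (b * b).sum()))
    if denom == 0.0:
        raise DegenerateInputError("zero-variance patch or template")
    r = float((a * b).sum() / denom)
    return min(max(r, 0.0), 1.0)


def _sequential_eye_state(
    patch: np.ndarray, templates: Sequence[np.ndarray], threshold: float
) -> tuple[str, Optional[float]]:
    """Match a patch against templates in order, stopping at first acceptance."""
    try:
        best = 0.0
        for tmpl in templates:
            score = match_score(patch, tmpl)
            best = max(best, score)
            if score >= threshold:
                return OPEN, score
        return CLOSED, best
    except DegenerateInputError:
        # A flat patch (e.g. fully padded) carries no information.
        return UNCLASSIFIED, None


def classify_frame(
    scores_left: Sequence[float],
    scores_right: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[str, str, bool]:
    """Classify one frame from pre-computed per-template match scores.

    An eye is *open* as soon as a score reaches the threshold, scanning the
    scores in template order (equivalently: the maximum score reaches the
    threshold); it is *closed* when every score falls below.  Returns
    ``(left_state, right_state, combined_closed)``.
    """
    if len(scores_left) == 0 or len(scores_right) == 0:
        raise ClassificationError("score lists must be non-empty")
    if not (0.0 < threshold <= 1.0):
        raise ClassificationError(f"threshold must be in (0, 1], got {threshold}")

    def state(scores: Sequence[float]) -> str:
        for s in scores:
            if s >= threshold:
                return OPEN
        return CLOSED

    left = state(scores_left)
    right = state(scores_right)
    return left, right, (left == CLOSED and right == CLOSED)


def extract_patch(
    frame: np.ndarray, center: tuple[float, float], size: tuple[int, int]
) -> tuple[np.ndarray, bool]:
    """Cut a fixed-size patch centred on an (x, y) eye coordinate.

    Portions falling outside the frame are zero-padded; the second return
    value flags whether padding occurred.
    """
    h, w = size
    cx, cy = center
    y0 = int(round(cy)) - h // 2
    x0 = int(round(cx)) - w // 2
    patch = np.zeros((h, w), dtype=np.float64)
    ys0, ys1 = max(y0, 0), min(y0 + h, frame.shape[0])
    xs0, xs1 = max(x0, 0), min(x0 + w, frame.shape[1])
    padded = (ys0, xs0, ys1, xs1) != (y0, x0, y0 + h, x0 + w)
    if ys1 > ys0 and xs1 > xs0:
        patch[ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0] = frame[ys0:ys1, xs0:xs1]
    return patch, padded


def build_templates(
    frames: Sequence[np.ndarray],
    selections: Sequence[tuple[int, tuple[int, int, int, int], tuple[int, int, int, int]]],
    threshold: float = DEFAULT_THRESHOLD,
) -> CalibrationSet:
    """Create a calibration set from selected frames and eye regions.

    Parameters
    ----------
    frames
        Indexable sequence of 2-D grayscale frames.
    selections
        ``(frame_index, left_region, right_region)`` triples, regions given as
        ``(x, y, width, height)`` with a 0-based top-left origin, half-open.
    threshold
        Match-score acceptance cutoff stored on the calibration set.
    """
    if len(selections) == 0:
        raise CalibrationError("at least one template selection is required")
    pairs = []
    for frame_index, left_region, right_region in selections:
        if not (0 <= frame_index < len(frames)):
            raise CalibrationError(f"selected frame {frame_index} does not exist")
        frame = np.asarray(frames[frame_index], dtype=np.float64)
        patches = []
        for region in (left_region, right_region):
            x, y, rw, rh = region
            if rw <= 0 or rh <= 0:
                raise CalibrationError(f"empty region {region}")
            if x < 0 or y < 0 or x + rw > frame.shape[1] or y + rh > frame.shape[0]:
                raise CalibrationError(
                    f"region {region} exceeds frame bounds {frame.shape[::-1]}"
                )
            patches.append(frame[y : y + rh, x : x + rw].copy())
        pairs.append(TemplatePair(left=patches[0], right=patches[1], source_frame=frame_index))
    return CalibrationSet(pairs=tuple(pairs), threshold=threshold)


def classify_sequence(
    video: Sequence[np.ndarray],
    calibration: CalibrationSet,
    landmarks: LandmarkProvider,
    fps: float = 60.0,
    source_id: str = "",
) -> EyeStateSeries:
    """Classify every frame of a video into per-eye open/closed states.

    Frames for which the landmark provider returns ``None`` remain
    unclassified with ``landmark_found=False``.  Patch size is taken from the
    calibration templates; patches partially outside the frame are zero-padded
    and flagged.
    """
    size = calibration.patch_size
    n = len(video)
    if n > 0:
        frame0 = np.asarray(video[0])
        if size[0] > frame0.shape[0] or size[1] > frame0.shape[1]:
            raise ConfigurationError(
                f"template patch {size} larger than video frames {frame0.shape}"
            )
    left_templates = [p.left for p in calibration.pairs]
    right_templates = [p.right for p in calibration.pairs]
    out = []
    for i in range(n):
        frame = np.asarray(video[i], dtype=np.float64)
        centers = landmarks(i, frame)
        if centers is None:
            out.append(FrameClassification(frame_index=i, landmark_found=False))
            continue
        (lx, ly), (rx, ry) = centers
        lpatch, lpad = extract_patch(frame, (lx, ly), size)
        rpatch, rpad = extract_patch(frame, (rx, ry), size)
        lstate, lscore = _sequential_eye_state(lpatch, left_templates, calibration.threshold)
        rstate, rscore = _sequential_eye_state(rpatch, right_templates, calibration.threshold)
        out.append(
            FrameClassification(
                frame_index=i,
                left_state=lstate,
                right_state=rstate,
                best_score_left=lscore,
                best_score_right=rscore,
                landmark_found=True,
                patch_padded=lpad or rpad,
            )
        )
    return EyeStateSeries(frames=tuple(out), fps=fps, source_id=source_id)


def apply_overrides(
    series: EyeStateSeries,
    overrides: Sequence[tuple[int, int, str]],
) -> EyeStateSeries:
    """Apply manual state corrections to a classified series.

    Each override is ``(frame_start, frame_end, state)`` with an inclusive
    frame range and state ``open`` or ``closed``; both eyes take the given
    state.  Later overrides win where ranges overlap; untouched frames are
    returned unchanged.
    """
    states: dict[int, str] = {}
    n = len(series)
    for start, end, state in overrides:
        if state not in (OPEN, CLOSED):
            raise OverrideError(f"override state must be open or closed, got {state!r}")
        if start < 0 or end >= n or start > end:
            raise OverrideError(
                f"override range [{start}, {end}] outside series of {n} frames"
            )
        for i in range(start, end + 1):
            states[i] = state
    if not states:
        return series
    frames = list(series.frames)
    for i, state in states.items():
        frames[i] = replace(frames[i], left_state=state, right_state=state)
    return EyeStateSeries(frames=tuple(frames), fps=series.fps, source_id=series.source_id)


def series_from_mask(
    closed: np.ndarray,
    fps: float = 60.0,
    known: Optional[np.ndarray] = None,
    source_id: str = "mask",
) -> EyeStateSeries:
    """Build an :class:`EyeStateSeries` from a boolean closed-frames mask.

    Convenience for analysing a combined open/closed signal directly (e.g. a
    thresholded synthetic aperture trace).  ``known=False`` frames become
    unclassified.
    """
    closed = np.asarray(closed, dtype=bool)
    if known is None:
        known = np.ones_like(closed)
    frames = []
    for i, (c, k) in enumerate(zip(closed, np.asarray(known, dtype=bool))):
        if not k:
            frames.append(FrameClassification(frame_index=i, landmark_found=False))
        else:
            state = CLOSED if c else OPEN
            frames.append(
                FrameClassification(
                    frame_index=i,
                    left_state=state,
                    right_state=state,
                    landmark_found=True,
                )
            )
    return EyeStateSeries(frames=tuple(frames), fps=fps, source_id=source_id)
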