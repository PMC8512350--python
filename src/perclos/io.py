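"""File formats: video input, calibration YAML, override CSV, run manifests.

Video input is either a directory of ordered PNG frames or an MP4 file
(decoded through imageio when an ffmpeg backend is available); frames are
converted to grayscale float in [0, 1] on read, indexed from 0.

The calibration file is YAML::

    threshold: 0.68
    eye_centers:            # optional; enables the static landmark provider
      left: [32.0, 32.0]
      right: [64.0, 32.0]
    templates:
      - frame: 12
        left:  {x: 18, y: 18, width: 28, height: 28}
        right: {x: 50, y: 18, width: 28, height: 28}

Regions are 0-based, top-left origin, half-open.  The override file is a CSV
with columns ``frame_start, frame_end, state`` (inclusive range; state open or
closed), replacing the interactive manual-correction step.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .classify import CalibrationSet, build_templates

__all__ = [
    "VideoReadError",
    "read_video",
    "write_frames",
    "load_calibration",
    "save_calibration",
    "load_overrides",
    "save_overrides",
    "StaticEyeCenters",
    "write_manifest",
]


class VideoReadError(IOError):
    """The video path could not be decoded into frames."""


def _to_gray01(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    img = img.astype(np.float64)
    if img.max() > 1.0:
        img = img / 255.0
    return img


def read_video(path) -> np.ndarray:
    """Read an MP4 file or a PNG-sequence directory into an (n, h, w) stack."""
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise VideoReadError(f"no PNG frames found in {path}")
        frames = [_to_gray01(iio.imread(f)) for f in files]
    elif path.is_file():
        try:
            frames = [_to_gray01(f) for f in iio.imiter(path)]
        except Exception as exc:  # decoder missing or corrupt container
            raise VideoReadError(f"cannot decode video {path}: {exc}") from exc
        if not frames:
            raise VideoReadError(f"no frames decoded from {path}")
    else:
        raise VideoReadError(f"video path {path} does not exist")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise VideoReadError(f"inconsistent frame shapes in {path}: {shapes}")
    return np.stack(frames)


def write_frames(directory, frames: Sequence[np.ndarray]) -> list[Path]:
    """Write frames as zero-padded 8-bit grayscale PNGs (frame_000000.png...)."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        img = np.clip(np.asarray(frame, dtype=np.float64), 0.0, 1.0)
        out = directory / f"frame_{i:06d}.png"
        iio.imwrite(out, (img * 255).round().astype(np.uint8))
        paths.append(out)
    return paths


def save_calibration(
    path,
    selections: Sequence[tuple[int, tuple[int, int, int, int], tuple[int, int, int, int]]],
    threshold: float = 0.68,
    eye_centers: Optional[tuple[tuple[float, float], tuple[float, float]]] = None,
) -> None:
    """Write a calibration YAML from template selections."""
    doc: dict = {
        "threshold": float(threshold),
        "templates": [
            {
                "frame": int(frame),
                "left": dict(zip(("x", "y", "width", "height"), map(int, left))),
                "right": dict(zip(("x", "y", "width", "height"), map(int, right))),
            }
            for frame, left, right in selections
        ],
    }
    if eye_centers is not None:
        doc["eye_centers"] = {
            "left": [float(v) for v in eye_centers[0]],
            "right": [float(v) for v in eye_centers[1]],
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def load_calibration(
    path, frames: Sequence[np.ndarray]
) -> tuple[CalibrationSet, Optional["StaticEyeCenters"]]:
    """Build a calibration set (and optional static landmark provider) from YAML."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    selections = []
    for t in doc["templates"]:
        regions = []
        for side in ("left", "right"):
            r = t[side]
            regions.append((int(r["x"]), int(r["y"]), int(r["width"]), int(r["height"])))
        selections.append((int(t["frame"]), regions[0], regions[1]))
    calibration = build_templates(frames, selections, threshold=float(doc.get("threshold", 0.68)))
    provider = None
    if "eye_centers" in doc:
        ec = doc["eye_centers"]
        provider = StaticEyeCenters(tuple(ec["left"]), tuple(ec["right"]))
    return calibration, provider


class StaticEyeCenters:
    """Landmark provider with fixed eye centres (fixed camera geometry)."""

    def __init__(self, left: tuple[float, float], right: tuple[float, float]):
        self.left = tuple(left)
        self.right = tuple(right)

    def __call__(self, frame_index, frame=None):
        return self.left, self.right


def load_overrides(path) -> list[tuple[int, int, str]]:
    """Read manual-correction ranges from CSV (frame_start, frame_end, state)."""
    df = pd.read_csv(path)
    missing = [c for c in ("frame_start", "frame_end", "state") if c not in df.columns]
    if missing:
        raise ValueError(f"override file missing columns: {missing}")
    return [
        (int(r.frame_start), int(r.frame_end), str(r.state).strip().lower())
        for r in df.itertuples()
    ]


def save_overrides(path, overrides: Sequence[tuple[int, int, str]]) -> None:
    pd.DataFrame(overrides, columns=["frame_start", "frame_end", "state"]).to_csv(
        path, index=False
    )


def write_manifest(path, payload: dict) -> None:
    """Write a reproducibility manifest (config, seeds, library versions)."""
    import statsmodels

    from . import __version__

    manifest = {
        "versions": {
            "perclos": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        **payload,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str), encoding="utf-8")
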