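"""Frame ingestion and coordinate conversion.

Videos are decoded into a :class:`FrameSequence` of 2-D grayscale intensity
arrays. Two sources are supported: a container file decodable by imageio
(MP4/AVI, if a suitable plugin is present) and a directory of numbered image
files, which is how the synthetic generator stores scenes.

Coordinate convention, shared by every module in this package: ``(x, y)`` is
``(column, row)``, origin at the top-left, 0-based, pixel centers at integer
coordinates.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

__all__ = ["FrameSequence", "read_frames", "to_grayscale", "pixels_to_metric"]

#: ITU-R BT.601 luminance weights for RGB -> intensity.
_LUMA = np.array([0.299, 0.587, 0.114])

_NUM_RE = re.compile(r"(\d+)")


@dataclass
class FrameSequence:
    """Ordered grayscale frames with timing and spatial calibration.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``, float intensity.
    frame_rate
        Frames per second; must be positive.
    metric_scale
        Meters per pixel, or ``None`` when no calibration is available.
    """

    frames: np.ndarray
    frame_rate: float
    metric_scale: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n, height, width) stack, got shape {self.frames.shape}"
            )
        if len(self.frames) < 2:
            raise ValueError("a FrameSequence needs at least 2 frames (flow uses frame pairs)")
        if not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.metric_scale is not None and not self.metric_scale > 0:
            raise ValueError(f"metric_scale must be positive, got {self.metric_scale}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return len(self.frames) / self.frame_rate

    def times(self) -> np.ndarray:
        """Time stamp (s) of each frame."""
        return np.arange(len(self.frames)) / self.frame_rate


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an image to float64 grayscale intensity.

    Color images use BT.601 luminance weighting (0.299 R + 0.587 G + 0.114 B);
    already-gray images pass through unchanged (as float). The conversion is
    deterministic and monotone in luminance.
    """
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame.astype(np.float64)
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        return frame[..., :3].astype(np.float64) @ _LUMA
    raise ValueError(f"cannot interpret array of shape {frame.shape} as an image")


def _numeric_key(p: Path) -> tuple:
    """Sort key ordering file names by embedded integers (frame_2 < frame_10)."""
    parts = _NUM_RE.split(p.name)
    return tuple(int(s) if s.isdigit() else s for s in parts)


def _list_image_dir(path: Path) -> list[Path]:
    exts = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}
    files = sorted((p for p in path.iterdir() if p.suffix.lower() in exts), key=_numeric_key)
    if not files:
        raise FileNotFoundError(f"no image files found in directory {path}")
    return files


def read_frames(
    path: str | Path,
    start: int = 0,
    count: int | None = None,
    frame_rate: float | None = None,
    metric_scale: float | None = None,
) -> FrameSequence:
    """Decode ``count`` consecutive grayscale frames starting at ``start``.

    ``path`` may be a video container or a directory of numbered images. For
    containers the frame rate is read from the metadata; for image directories
    it must be supplied (the synthetic generator records it in the scene config
    it writes alongside the frames).

    If fewer frames than requested exist past ``start``, the sequence is
    truncated with a warning; fewer than 2 remaining frames is an error.
    """
    path = Path(path)
    if start < 0:
        raise ValueError(f"start must be >= 0, got {start}")
    if count is not None and count < 2:
        raise ValueError(f"count must be >= 2, got {count}")
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")

    if path.is_dir():
        files = _list_image_dir(path)
        n_avail = len(files)
        sel = files[start : start + count if count is not None else None]
        if count is not None and len(sel) < count:
            warnings.warn(
                f"requested {count} frames at start={start} but only {n_avail - start} "
                f"available; truncating",
                stacklevel=2,
            )
        if len(sel) < 2:
            raise ValueError(
                f"need at least 2 frames, got {len(sel)} (start={start}, {n_avail} in {path})"
            )
        frames = np.stack([to_grayscale(iio.imread(f)) for f in sel])
        if frame_rate is None:
            frame_rate = 30.0
        return FrameSequence(frames, frame_rate=frame_rate, metric_scale=metric_scale)

    try:
        raw = iio.imread(path, index=None)
        meta = iio.immeta(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"could not decode {path}: {exc}") from exc
    if frame_rate is None:
        frame_rate = float(meta.get("fps", 30.0))
    raw = np.asarray(raw)
    if raw.ndim == 2:
        raise ValueError(f"{path} contains a single image, not a frame sequence")
    if raw.ndim == 3 and raw.shape[-1] in (3, 4):
        raise ValueError(f"{path} contains a single color image, not a frame sequence")
    n_avail = raw.shape[0]
    stop = n_avail if count is None else start + count
    sel = raw[start:stop]
    if count is not None and len(sel) < count:
        warnings.warn(
            f"requested {count} frames at start={start} but only {n_avail - start} "
            f"available; truncating",
            stacklevel=2,
        )
    if len(sel) < 2:
        raise ValueError(f"need at least 2 frames, got {len(sel)} from {path}")
    frames = np.stack([to_grayscale(f) for f in sel])
    return FrameSequence(frames, frame_rate=frame_rate, metric_scale=metric_scale)


def pixels_to_metric(
    point: Sequence[float] | np.ndarray, metric_scale: float | None
) -> np.ndarray:
    """Convert pixel coordinates to meters by uniform scaling.

    ``point`` is ``(x, y)`` or an array of points with ``(x, y)`` last axis.
    A single scalar meters-per-pixel calibration is applied component-wise;
    parallax and lens distortion are not modeled.
    """
    if metric_scale is None:
        raise ValueError(
            "metric_scale is not set: supply a meters-per-pixel calibration "
            "(config key `metric_scale`) to convert positions to metric space"
        )
    if not metric_scale > 0:
        raise ValueError(f"metric_scale must be positive, got {metric_scale}")
    return np.asarray(point, dtype=np.float64) * metric_scale
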