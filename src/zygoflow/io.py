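"""Calibrated image-stack I/O, annotations and run configuration.

A :class:`FrameStack` is the canonical in-memory container for a time-lapse
recording: an ordered set of equally sized grayscale frames plus the two
calibration constants every downstream metric needs — micrometres per pixel
and minutes per frame.  Intensities are always normalized to [0, 1] on load
so that 8- and 16-bit recordings of the same scene are interchangeable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from imageio.v3 import imread

__all__ = [
    "FrameStack",
    "Annotations",
    "ConfigError",
    "load_stack",
    "save_stack",
    "write_metrics",
    "load_config",
    "merge_overrides",
    "normalize_intensity",
]

_FRAME_EXTENSIONS = {".tif", ".tiff", ".png"}


class ConfigError(ValueError):
    """Invalid configuration or calibration."""


def normalize_intensity(arr: np.ndarray) -> np.ndarray:
    """Map an image to float64 in [0, 1].

    Integer images are divided by their dtype maximum, so an 8-bit and a
    16-bit capture of the same scene normalize to the same values up to
    quantization.  Float images already within [0, 1] are passed through
    unchanged, which makes the operation idempotent; float images with a
    larger range are scaled by their maximum.
    """
    a = np.asarray(arr)
    if np.issubdtype(a.dtype, np.integer):
        return a.astype(np.float64) / np.iinfo(a.dtype).max
    a = a.astype(np.float64, copy=False)
    if a.size and a.max() > 1.0:
        return a / a.max()
    return a


@dataclass
class FrameStack:
    """An ordered grayscale time-lapse with physical calibration.

    Parameters
    ----------
    frames
        Array of shape (T, H, W), float, intensities in [0, 1].
    pixel_size
        Micrometres per pixel (> 0).
    frame_interval
        Minutes between consecutive frames (> 0).
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ConfigError("pixel_size and frame_interval must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape[1:]

    @property
    def timestamps(self) -> np.ndarray:
        """Acquisition time of each frame in minutes (index x interval)."""
        return np.arange(len(self), dtype=float) * self.frame_interval


@dataclass
class Annotations:
    """Optional per-recording manual annotations.

    ``pb2_position`` maps frame index to the (row, col) pixel position of
    the second polar body; ``pb2_radius`` is its apparent radius in pixels.
    ``stage_frames`` maps named events (``one_indent``, ``two_indents``,
    ``pnebd``) to frame indices.  ``cell_split`` maps frame index to a line
    ((row, col), (row, col)) dividing a two-cell image into daughters.
    """

    pb2_position: dict = field(default_factory=dict)
    pb2_radius: Optional[float] = None
    stage_frames: dict = field(default_factory=dict)
    cell_split: dict = field(default_factory=dict)

    def validate(self, n_frames: int) -> None:
        idx = list(self.pb2_position) + list(self.stage_frames.values())
        idx += list(self.cell_split)
        for i in idx:
            if not (0 <= int(i) < n_frames):
                raise ValueError(f"annotation frame {i} outside stack of {n_frames}")


def _read_frame_dir(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS
    )
    if not files:
        raise FileNotFoundError(f"no image frames in {path}")
    frames = [np.asarray(imread(f)) for f in files]
    return np.stack(frames)


def load_stack(
    path,
    pixel_size: Optional[float] = None,
    frame_interval: Optional[float] = None,
) -> FrameStack:
    """Read a multi-page TIFF or a directory of per-frame images.

    Calibration may be omitted when the TIFF was written by
    :func:`save_stack`, which embeds it in the image description.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    meta = {}
    if path.is_dir():
        frames = _read_frame_dir(path)
    else:
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            desc = tf.pages[0].description
            if desc:
                try:
                    meta = json.loads(desc)
                except (TypeError, json.JSONDecodeError):
                    meta = {}
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"expected grayscale frames, got shape {frames.shape}")
    if frames.shape[0] < 2:
        raise ValueError("a stack needs at least 2 frames for motion analysis")
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size")
    frame_interval = (
        frame_interval if frame_interval is not None else meta.get("frame_interval")
    )
    if pixel_size is None or frame_interval is None:
        raise ConfigError("pixel_size and frame_interval must be supplied")
    return FrameStack(
        frames=np.stack([normalize_intensity(f) for f in frames]),
        pixel_size=float(pixel_size),
        frame_interval=float(frame_interval),
    )


def save_stack(stack: FrameStack, path) -> None:
    """Write a stack as a float32 multi-page TIFF with embedded calibration."""
    meta = {"pixel_size": stack.pixel_size, "frame_interval": stack.frame_interval}
    tifffile.imwrite(
        Path(path),
        stack.frames.astype(np.float32),
        description=json.dumps(meta),
        compression="deflate",
    )


def write_metrics(records, path) -> None:
    """Write per-frame or per-event metrics as a CSV with a header row.

    ``records`` is a DataFrame or a sequence of mappings.  Column names are
    expected to carry their units (e.g. ``area_um2``, ``speed_um_min``).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
    if df.empty:
        raise ValueError("no records to write")
    df.to_csv(Path(path), index=False, float_format="%.10g")


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def merge_overrides(cfg: dict, overrides: Mapping[str, object]) -> dict:
    """Apply dotted-key overrides (e.g. ``piv.initial_window=32``) to a config."""
    out = json.loads(json.dumps(cfg))
    for key, value in overrides.items():
        node = out
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    return out
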