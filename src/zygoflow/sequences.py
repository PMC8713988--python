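"""Detection of shape sequences and the cytokinetic elongation onset.

A "shape sequence" is a rounder-distorted-rounder cycle of the cell
profile.  Operationally: the diameter-SD trace shows a trough-peak-trough
excursion during which at least one of the 18 diameters extends by at least
1.5 um (the detection rule) and then retracts.  The "first step" of
cytokinetic elongation is the earliest 1 um-or-more increase of the
elongation diameter within a 2 minute interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .morphometrics import DIAMETER_ANGLES, RadialProfile

__all__ = [
    "ShapeSequence",
    "ElongationEvent",
    "detect_sequences",
    "find_elongation_axis",
    "detect_first_step",
    "detect_indents",
]


@dataclass
class ShapeSequence:
    """One detected in-out-in diameter cycle."""

    angle: float             # diameter angle (deg) with the maximal in-out-in change
    start_frame: int
    peak_frame: int
    end_frame: int
    out_amplitude: float     # um, extension: d(peak) - d(start)
    in_amplitude: float      # um, retraction: d(peak) - d(end)
    duration: float          # minutes

    def __post_init__(self):
        if not (self.start_frame < self.peak_frame < self.end_frame):
            raise ValueError("sequence frames must be ordered start < peak < end")
        if self.out_amplitude < 1.5 or self.in_amplitude <= 0:
            raise ValueError("sequence violates the >=1.5 um in-out-in rule")

    @property
    def max_inoutin(self) -> float:
        """min(extension, retraction) at the reported angle, um."""
        return min(self.out_amplitude, self.in_amplitude)


@dataclass
class ElongationEvent:
    """Cytokinetic elongation: axis, extent, and the rapid first step."""

    first_step_frame: Optional[int]
    axis_angle: Optional[float]      # deg; None when indeterminate
    extension: float                 # um along the axis
    duration: float                  # minutes from t0 to t1
    one_indent_frame: Optional[int] = None
    tie: bool = False


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad:pad + x.size]


def detect_sequences(
    diam_series: np.ndarray,
    sd_series: np.ndarray,
    min_extension: float = 1.5,
    smooth_window: int = 3,
    min_prominence: float = 0.3,
    retraction_floor: float = 0.5,
    frame_interval: float = 1.0,
    angles: Sequence[float] = tuple(DIAMETER_ANGLES),
) -> List[ShapeSequence]:
    """Detect in-out-in cycles from diameter time series.

    Parameters
    ----------
    diam_series
        (18, T) diameters in um, one row per 10-degree angle.
    sd_series
        (T,) diameter-SD trace in um; candidate cycles are its
        trough-peak-trough excursions after moving-average smoothing.
    min_extension
        Minimum rise of at least one diameter from trough to peak (um).
    retraction_floor
        Minimum fall from peak toward the second trough for the same
        diameter to count as a retraction (um); rejects measurement noise.

    One sequence is emitted per qualifying SD triplet, carrying the angle
    whose in-out-in change (min of extension and retraction) is maximal;
    ties go to the smaller angle.
    """
    d = np.asarray(diam_series, dtype=float)
    sd = np.asarray(sd_series, dtype=float)
    T = sd.size
    if T < 3:
        raise ValueError("need at least 3 frames")
    if smooth_window > T:
        raise ValueError("series shorter than the smoothing window")
    if d.shape[1] != T:
        raise ValueError("diameter and SD series lengths differ")
    angles = np.asarray(angles, dtype=float)

    smooth = _moving_average(sd, smooth_window)
    peaks, _ = find_peaks(smooth, prominence=min_prominence)
    sequences: List[ShapeSequence] = []
    for j, p in enumerate(peaks):
        left_bound = peaks[j - 1] if j > 0 else 0
        right_bound = peaks[j + 1] if j + 1 < len(peaks) else T - 1
        if p - left_bound < 1 or right_bound - p < 1:
            continue
        # widest-extent troughs: the minima of the smoothed SD on each side
        start = left_bound + int(np.argmin(smooth[left_bound:p]))
        end = p + 1 + int(np.argmin(smooth[p + 1:right_bound + 1]))
        out_amp = d[:, p] - d[:, start]
        in_amp = d[:, p] - d[:, end]
        qualifies = (out_amp >= min_extension) & (in_amp >= retraction_floor)
        if not qualifies.any():
            continue
        inoutin = np.where(qualifies, np.minimum(out_amp, in_amp), -np.inf)
        best = int(np.argmax(inoutin))  # argmax takes the first (smallest angle) tie
        sequences.append(ShapeSequence(
            angle=float(angles[best]),
            start_frame=start, peak_frame=int(p), end_frame=end,
            out_amplitude=float(out_amp[best]),
            in_amplitude=float(in_amp[best]),
            duration=float((end - start) * frame_interval),
        ))
    return sequences


def find_elongation_axis(
    profiles: Sequence[RadialProfile], t0: int, t1: int
) -> ElongationEvent:
    """Diameter with the greatest extension between frames t0 and t1.

    Returns an :class:`ElongationEvent` whose ``axis_angle`` is None when
    no diameter extended (indeterminate axis); ties resolve to the smaller
    angle and set ``tie``.
    """
    if t0 >= t1:
        raise ValueError("need t0 < t1")
    by_frame = {p.frame_index: p for p in profiles}
    missing = [t for t in (t0, t1) if t not in by_frame]
    if missing:
        raise ValueError(f"missing radial profiles for frames {missing}")
    ext = by_frame[t1].diameters - by_frame[t0].diameters
    best = int(np.argmax(ext))
    extension = float(ext[best])
    if extension <= 0:
        return ElongationEvent(None, None, 0.0, 0.0)
    tie = bool(np.sum(np.isclose(ext, ext[best], atol=1e-9)) > 1)
    return ElongationEvent(
        first_step_frame=None,
        axis_angle=float(DIAMETER_ANGLES[best]),
        extension=extension,
        duration=0.0,
        tie=tie,
    )


def detect_first_step(
    diam_series: np.ndarray,
    frame_interval: float,
    threshold: float = 1.0,
    window: float = 2.0,
) -> Optional[int]:
    """Earliest frame where the diameter rises by >= ``threshold`` um within
    ``window`` minutes; None when no such frame exists.

    When the frame interval does not divide the window, the nearest whole
    number of frames (>= 1) is used and recorded via a warning.
    """
    d = np.asarray(diam_series, dtype=float)
    w_exact = window / frame_interval
    w = max(1, int(round(w_exact)))
    if abs(w - w_exact) > 1e-9:
        warnings.warn(
            f"window of {window} min is {w_exact:.2f} frames; using {w} frames"
        )
    if d.size <= w:
        raise ValueError("series too short for the detection window")
    diff = d[w:] - d[:-w]
    hits = np.nonzero((diff >= threshold) & (diff > 0))[0]
    return int(hits[0]) if hits.size else None


def detect_indents(outline, min_depth: float, pixel_size: float,
                   n_angles: int = 360) -> List[tuple]:
    """Concavities of an outline: angles where the boundary dips below the
    convex hull by at least ``min_depth`` um.

    Supports automatic one-/two-indent staging when manual annotations are
    absent.  Returns a list of (angle_deg, depth_um) at local depth maxima.
    """
    from shapely.geometry import Polygon

    from .morphometrics import _ray_polygon_distance

    poly = Polygon(np.column_stack([outline.boundary[:, 1], outline.boundary[:, 0]]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    hull = poly.convex_hull
    coa_xy = (outline.centre[1], outline.centre[0])
    reach = 4.0 * np.sqrt(hull.area)
    grid = np.arange(n_angles) * (360.0 / n_angles)
    depth = np.array([
        _ray_polygon_distance(hull, coa_xy, a, reach)
        - _ray_polygon_distance(poly, coa_xy, a, reach)
        for a in grid
    ]) * pixel_size
    # circular peak finding: pad a quarter turn on each side
    pad = n_angles // 4
    wrapped = np.concatenate([depth[-pad:], depth, depth[:pad]])
    peaks, props = find_peaks(wrapped, height=min_depth)
    hits = []
    for p, h in zip(peaks, props["peak_heights"]):
        idx = (p - pad) % n_angles
        if pad <= p < pad + n_angles:
            hits.append((float(grid[idx]), float(h)))
    return hits
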