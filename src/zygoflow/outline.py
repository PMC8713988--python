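"""Cell-boundary extraction by Sobel edges + dynamic programming in polar
coordinates.

The frame is unwrapped into a polar (angle x radius) grid about a seed
centre.  A Sobel gradient-magnitude map, normalized to a maximum of 1 so
that the result is invariant to global intensity scaling, supplies the edge
evidence.  The boundary is the radius function r(theta) over A angular bins
maximizing

    sum_theta edge(theta, r(theta))
      - smoothing      * sum_theta (r(theta+1) - r(theta))^2
      - temporal_weight * sum_theta (r(theta) - r_prev(theta))^2

subject to circular closure r(A) = r(0) and a bounded step |dr| <= max_step
per angular bin.  Closure is enforced by running the DP once per admissible
start radius on a coarse grid (every 4th radius) and refining around the
best start.  The temporal term biases the outline toward the previous
frame's outline during tracking, which is what makes the detector robust on
low-contrast time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.draw import polygon2mask
from skimage.filters import sobel

from ._geom import polygon_centroid, shoelace_area, unit_direction

__all__ = [
    "Outline",
    "SegmentationFailure",
    "detect_outline",
    "track_outlines",
    "polygon_area",
    "outline_to_mask",
    "outline_radii",
]


class SegmentationFailure(RuntimeError):
    """No admissible boundary found in a frame (e.g. zero edge energy)."""


@dataclass
class Outline:
    """A closed cell (or zona) boundary in one frame.

    ``boundary`` is an (N, 2) array of (row, col) pixel coordinates forming
    a simple closed polygon (N >= 36, one vertex per angular bin).
    ``centre`` is the polygon's area centroid (the CoA).
    """

    boundary: np.ndarray
    frame_index: int = 0
    target: str = "cell"
    interpolated: bool = False
    centre: np.ndarray = field(init=False)

    def __post_init__(self):
        self.boundary = np.asarray(self.boundary, dtype=float)
        if self.boundary.ndim != 2 or self.boundary.shape[1] != 2:
            raise ValueError("boundary must be an (N, 2) array")
        if self.boundary.shape[0] < 36:
            raise ValueError("boundary needs >= 36 vertices")
        self.centre = polygon_centroid(self.boundary)

    @property
    def n_points(self) -> int:
        return self.boundary.shape[0]


def outline_radii(outline: Outline, centre=None) -> np.ndarray:
    """Distance of each boundary vertex from a centre (defaults to the CoA)."""
    c = outline.centre if centre is None else np.asarray(centre, dtype=float)
    return np.linalg.norm(outline.boundary - c, axis=1)


def polygon_area(outline: Outline, pixel_size: float = 1.0) -> float:
    """Enclosed area in um^2 (shoelace), independent of vertex orientation."""
    a_px = abs(shoelace_area(outline.boundary))
    if a_px < 10.0:
        raise ValueError(f"degenerate polygon: area {a_px:.2f} px^2 < 10 px^2")
    return a_px * pixel_size**2


def outline_to_mask(outline: Outline, shape) -> np.ndarray:
    """Rasterize an outline into a boolean interior mask of a given shape."""
    return polygon2mask(shape, outline.boundary)


def _edge_map(frame: np.ndarray) -> np.ndarray:
    edge = sobel(np.asarray(frame, dtype=float))
    m = edge.max()
    if m > 0:
        edge = edge / m
    return edge


def _polar_sample(img, centre, radii, n_angles):
    """Sample ``img`` on a polar grid -> array of shape (n_angles, n_radii)."""
    angles = np.arange(n_angles) * (360.0 / n_angles)
    d = unit_direction(angles)  # (A, 2)
    rows = centre[0] + np.outer(d[:, 0], radii)
    cols = centre[1] + np.outer(d[:, 1], radii)
    return map_coordinates(img, [rows, cols], order=1, mode="nearest")


def _prev_radius_profile(prev: Outline, centre, n_angles) -> np.ndarray:
    """Radius of a previous outline about ``centre`` at each angular bin."""
    rel = prev.boundary - np.asarray(centre, dtype=float)
    theta = np.degrees(np.arctan2(rel[:, 1], -rel[:, 0])) % 360.0
    rad = np.linalg.norm(rel, axis=1)
    order = np.argsort(theta)
    theta_s, rad_s = theta[order], rad[order]
    # periodic linear interpolation onto the angular grid
    theta_ext = np.concatenate([theta_s - 360.0, theta_s, theta_s + 360.0])
    rad_ext = np.concatenate([rad_s, rad_s, rad_s])
    grid = np.arange(n_angles) * (360.0 / n_angles)
    return np.interp(grid, theta_ext, rad_ext)


def _dp_closed_path(node_score: np.ndarray, smoothing: float, max_step: int,
                    start_indices: Sequence[int]):
    """Best closed path through an (A, R) node-score lattice.

    Transitions are limited to |dr| <= max_step radial bins per angular step
    and pay ``smoothing * dr^2``; the path must return to its start radius
    (the closing transition pays the same penalty).  Returns
    (best_total, best_path_indices) over the given start radii.
    """
    A, R = node_score.shape
    offsets = np.arange(-max_step, max_step + 1)
    trans_pen = smoothing * offsets.astype(float) ** 2
    best_total, best_path = -np.inf, None
    for s in start_indices:
        score = np.full(R, -np.inf)
        score[s] = node_score[0, s]
        back = np.zeros((A, R), dtype=np.int8)
        for a in range(1, A):
            cand = np.full((offsets.size, R), -np.inf)
            for k, dr in enumerate(offsets):
                if dr >= 0:
                    cand[k, dr:] = score[: R - dr] - trans_pen[k]
                elif R + dr > 0:
                    cand[k, : R + dr] = score[-dr:] - trans_pen[k]
            k_best = np.argmax(cand, axis=0)
            score = cand[k_best, np.arange(R)] + node_score[a]
            back[a] = k_best.astype(np.int8)
        # closing transition back to the start radius
        lo, hi = max(0, s - max_step), min(R, s + max_step + 1)
        close = score[lo:hi] - smoothing * (np.arange(lo, hi) - s) ** 2
        if not np.isfinite(close).any():
            continue
        r_last = lo + int(np.argmax(close))
        total = float(close[r_last - lo])
        if total > best_total:
            path = np.empty(A, dtype=int)
            path[A - 1] = r_last
            for a in range(A - 1, 0, -1):
                path[a - 1] = path[a] - (int(back[a, path[a]]) - max_step)
            best_total, best_path = total, path
    return best_total, best_path


def detect_outline(
    frame: np.ndarray,
    seed_centre,
    r_min: float,
    r_max: float,
    prev: Optional[Outline] = None,
    temporal_weight: float = 0.0,
    smoothing: float = 0.05,
    n_angles: int = 360,
    max_step: int = 2,
    coarse_every: int = 4,
    frame_index: int = 0,
    target: str = "cell",
    edge_polarity: str = "any",
    pb2_angle: Optional[float] = None,
    pb2_extra_px: float = 0.0,
    pb2_halfwidth_deg: float = 15.0,
) -> Outline:
    """Detect a closed boundary around ``seed_centre`` in one frame.

    Parameters mirror the objective in the module docstring.  ``prev``
    supplies the previous frame's outline for the temporal bias term; with
    ``temporal_weight -> inf`` the result converges to ``prev``.

    ``edge_polarity`` selects edges by the sign of the radial intensity
    gradient: ``"falling"`` keeps bright-to-dark transitions going outward
    (a cell membrane against a darker background, or the outer zona edge
    seen from inside the ring), ``"rising"`` the opposite, ``"any"`` uses
    the plain gradient magnitude.  This is how the inner vs outer zona
    pellucida edge is chosen.

    When a second polar body should be enclosed, ``pb2_angle`` (degrees)
    dilates the admissible radius band by ``pb2_extra_px`` within
    ``pb2_halfwidth_deg`` of that direction; elsewhere the band is
    unchanged, so the 2PB bulge can be included without loosening the
    whole search.
    """
    frame = np.asarray(frame, dtype=float)
    H, W = frame.shape
    seed = np.asarray(seed_centre, dtype=float)
    if not (0 <= seed[0] < H and 0 <= seed[1] < W):
        raise ValueError("seed centre outside image")
    if not (0 < r_min < r_max):
        raise ValueError("need 0 < r_min < r_max")
    border = min(seed[0], seed[1], H - 1 - seed[0], W - 1 - seed[1])
    r_max = min(r_max, border)
    if r_max - r_min < 2:
        raise ValueError("radial band too narrow inside the image")

    r_top = float(r_max) + (float(pb2_extra_px) if pb2_angle is not None else 0.0)
    r_top = min(r_top, border)
    radii = np.arange(float(r_min), r_top + 1.0)
    edge = _polar_sample(_edge_map(frame), seed, radii, n_angles)  # (A, R)
    if edge_polarity != "any":
        intensity = _polar_sample(frame, seed, radii, n_angles)
        d_dr = np.gradient(intensity, axis=1)
        keep = d_dr < 0 if edge_polarity == "falling" else d_dr > 0
        edge = np.where(keep, edge, 0.0)
    if edge.max() <= 1e-12:
        raise SegmentationFailure("no edge energy in the radial band")
    node = edge.copy()
    if pb2_angle is not None and radii[-1] > r_max:
        # radii beyond r_max are admissible only near the 2PB direction
        grid_angles = np.arange(n_angles) * (360.0 / n_angles)
        ang_dist = np.abs((grid_angles - pb2_angle + 180.0) % 360.0 - 180.0)
        beyond = radii[None, :] > r_max
        blocked = beyond & (ang_dist[:, None] > pb2_halfwidth_deg)
        node[blocked] = -np.inf
    if prev is not None and temporal_weight > 0:
        prev_r = _prev_radius_profile(prev, seed, n_angles)
        node = node - temporal_weight * (radii[None, :] - prev_r[:, None]) ** 2

    R = radii.size
    coarse = list(range(0, R, max(1, coarse_every)))
    total, path = _dp_closed_path(node, smoothing, max_step, coarse)
    if path is not None:
        s0 = path[0]
        refine = [s for s in range(max(0, s0 - 3), min(R, s0 + 4)) if s not in coarse]
        total2, path2 = _dp_closed_path(node, smoothing, max_step, refine)
        if total2 > total:
            total, path = total2, path2
    if path is None:
        raise SegmentationFailure("no admissible closed path")
    if edge[np.arange(n_angles), path].sum() < 1e-6 * n_angles:
        raise SegmentationFailure("best path has no edge support")

    r_path = radii[path]
    d = unit_direction(np.arange(n_angles) * (360.0 / n_angles))
    boundary = seed + d * r_path[:, None]
    return Outline(boundary, frame_index=frame_index, target=target)


def track_outlines(
    stack,
    seed_centre,
    r_min: float,
    r_max: float,
    temporal_weight: float = 0.02,
    smoothing: float = 0.05,
    n_angles: int = 360,
    max_step: int = 2,
    target: str = "cell",
) -> List[Outline]:
    """Track the boundary through a stack, frame 0 without temporal bias.

    Each subsequent frame is seeded at the previous CoA and biased toward
    the previous outline.  Frames where segmentation fails are linearly
    interpolated (per angular bin) from the flanking successes and flagged
    ``interpolated``; if more than half the frames fail, tracking aborts.
    """
    outlines: List[Optional[Outline]] = []
    failed: List[int] = []
    prev: Optional[Outline] = None
    for i, frame in enumerate(stack.frames):
        seed = np.asarray(seed_centre, dtype=float) if prev is None else prev.centre
        try:
            out = detect_outline(
                frame, seed, r_min, r_max,
                prev=prev,
                temporal_weight=temporal_weight if prev is not None else 0.0,
                smoothing=smoothing, n_angles=n_angles, max_step=max_step,
                frame_index=i, target=target,
            )
            prev = out
            outlines.append(out)
        except SegmentationFailure:
            failed.append(i)
            outlines.append(None)
    if len(failed) > len(outlines) // 2:
        raise RuntimeError(
            f"segmentation failed on {len(failed)}/{len(outlines)} frames: {failed}"
        )
    if failed:
        _interpolate_failures(outlines, n_angles)
    return outlines  # type: ignore[return-value]


def _interpolate_failures(outlines: List[Optional[Outline]], n_angles: int) -> None:
    """Fill failed frames by per-bin linear interpolation between successes."""
    n = len(outlines)
    good = [i for i, o in enumerate(outlines) if o is not None]
    for i, o in enumerate(outlines):
        if o is not None:
            continue
        before = max((g for g in good if g < i), default=None)
        after = min((g for g in good if g > i), default=None)
        if before is None or after is None:
            src = outlines[after if before is None else before]
            filled = Outline(src.boundary.copy(), frame_index=i,
                             target=src.target, interpolated=True)
        else:
            a, b = outlines[before], outlines[after]
            w = (i - before) / (after - before)
            centre = (1 - w) * a.centre + w * b.centre
            ra = _prev_radius_profile(a, centre, n_angles)
            rb = _prev_radius_profile(b, centre, n_angles)
            r = (1 - w) * ra + w * rb
            d = unit_direction(np.arange(n_angles) * (360.0 / n_angles))
            filled = Outline(centre + d * r[:, None], frame_index=i,
                             target=a.target, interpolated=True)
        outlines[i] = filled
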