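"""Radial shape descriptors: 36 radii / 18 diameters about the CoA.

The cell outline is reduced to the distance from the centre of area to the
boundary along 36 rays at 10-degree steps.  Opposite rays are summed into
18 diameters, every one of which passes through the CoA by construction.
The standard deviation of the 18 diameters is the per-frame shape index
(zero for a circle, growing with distortion); ratios of perpendicular
diameters quantify elongation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from .outline import Outline

__all__ = [
    "RadialProfile",
    "radial_profile",
    "diameter_sd",
    "axis_ratio",
    "pb2_diameter",
    "profiles_to_table",
]

RAY_ANGLES = np.arange(0.0, 360.0, 10.0)
DIAMETER_ANGLES = np.arange(0.0, 180.0, 10.0)


@dataclass
class RadialProfile:
    """36 radii and 18 diameters (um) of one outline about its CoA."""

    frame_index: int
    radii: np.ndarray          # (36,) um, at 0, 10, ..., 350 degrees
    coa: np.ndarray            # (row, col) px
    pixel_size: float
    diameters: np.ndarray = field(init=False)  # (18,) um

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        if self.radii.shape != (36,):
            raise ValueError("expected exactly 36 radii")
        self.diameters = self.radii[:18] + self.radii[18:]

    def diameter_at(self, angle_deg: float) -> float:
        """Diameter (um) at the nearest 10-degree grid angle."""
        return float(self.diameters[_snap_diameter_index(angle_deg)])


def _snap_diameter_index(angle_deg: float) -> int:
    return int(np.round((angle_deg % 180.0) / 10.0)) % 18


def _ray_polygon_distance(poly: Polygon, coa_xy, angle_deg: float,
                          reach: float, farthest: bool = True) -> float:
    """Distance (px) from the CoA to the boundary along one ray."""
    from ._geom import unit_direction

    d = unit_direction(angle_deg)          # (row, col)
    dx, dy = d[1], d[0]                    # shapely x=col, y=row
    ray = LineString([coa_xy, (coa_xy[0] + reach * dx, coa_xy[1] + reach * dy)])
    hit = ray.intersection(poly.exterior)
    if hit.is_empty:
        raise ValueError(f"ray at {angle_deg} deg does not reach the boundary")
    pts = []
    for g in getattr(hit, "geoms", [hit]):
        if g.geom_type == "Point":
            pts.append(g)
        else:  # overlapping segment: take its endpoints
            pts.extend(Point(c) for c in g.coords)
    dists = [Point(coa_xy).distance(p) for p in pts]
    return max(dists) if farthest else min(dists)


def radial_profile(outline: Outline, pixel_size: float,
                   farthest_intersection: bool = True) -> RadialProfile:
    """Measure the 36 radii of an outline about its CoA.

    Concave outlines (e.g. during cytokinesis) can cross a ray more than
    once; by default the farthest intersection is used so that diameters
    grow monotonically under elongation.
    """
    poly = Polygon(np.column_stack([outline.boundary[:, 1], outline.boundary[:, 0]]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    coa_xy = (outline.centre[1], outline.centre[0])
    if not poly.contains(Point(coa_xy)):
        raise ValueError("CoA lies outside the outline polygon")
    reach = 4.0 * np.sqrt(poly.area)
    radii_px = np.array([
        _ray_polygon_distance(poly, coa_xy, a, reach, farthest_intersection)
        for a in RAY_ANGLES
    ])
    return RadialProfile(
        frame_index=outline.frame_index,
        radii=radii_px * pixel_size,
        coa=outline.centre.copy(),
        pixel_size=pixel_size,
    )


def diameter_sd(profile: RadialProfile) -> float:
    """Sample standard deviation (n-1 denominator) of the 18 diameters, um."""
    return float(np.std(profile.diameters, ddof=1))


def axis_ratio(profile: RadialProfile, angle_deg: float) -> float:
    """Diameter at ``angle`` divided by its perpendicular diameter.

    Off-grid angles snap to the nearest 10 degrees (a warning records the
    snap).  The ratio at ``angle`` times the ratio at ``angle + 90`` is
    exactly 1.
    """
    snapped = _snap_diameter_index(angle_deg) * 10.0
    if abs((angle_deg % 180.0) - snapped) > 1e-9 and abs((angle_deg % 180.0) - snapped) < 175.0:
        warnings.warn(f"axis_ratio: angle {angle_deg} snapped to {snapped} deg")
    num = profile.diameter_at(snapped)
    den = profile.diameter_at(snapped + 90.0)
    if den <= 0:
        raise ValueError("degenerate perpendicular diameter")
    return float(num / den)


def pb2_diameter(
    profile: RadialProfile,
    pb2_position,
    include_pb2_width: bool = False,
    pb2_radius_px: float = 0.0,
) -> Tuple[float, float]:
    """Diameter (um) through the CoA and the second polar body.

    The CoA-to-2PB direction is snapped to the nearest 10-degree ray.  With
    ``include_pb2_width`` the near radius is extended to the far edge of the
    2PB blob (distance from CoA to the 2PB centre plus its radius), giving
    the "2PB diameter + 2PB" convention.  Returns (length_um, ray_angle_deg).
    """
    from ._geom import angle_of

    if pb2_position is None:
        raise ValueError("2PB annotation missing")
    pb2 = np.asarray(pb2_position, dtype=float)
    raw = angle_of(pb2 - profile.coa)
    ray_idx = int(np.round(raw / 10.0)) % 36
    ray_angle = ray_idx * 10.0
    if abs((raw - ray_angle + 180.0) % 360.0 - 180.0) > 1e-9:
        warnings.warn(f"pb2 direction {raw:.1f} deg snapped to {ray_angle:.0f} deg")
    opposite = profile.radii[(ray_idx + 18) % 36]
    if include_pb2_width:
        near = (np.linalg.norm(pb2 - profile.coa) + pb2_radius_px) * profile.pixel_size
    else:
        near = profile.radii[ray_idx]
    return float(near + opposite), ray_angle


def profiles_to_table(profiles: List[RadialProfile], areas: Optional[List[float]] = None):
    """Flatten profiles into a per-frame metrics table (radii, diameters, SD)."""
    import pandas as pd

    rows = []
    for k, p in enumerate(profiles):
        row = {"frame": p.frame_index}
        row.update({f"radius_{int(a)}_um": r for a, r in zip(RAY_ANGLES, p.radii)})
        row.update({
            f"diameter_{int(a)}_um": d for a, d in zip(DIAMETER_ANGLES, p.diameters)
        })
        row["diameter_sd_um"] = diameter_sd(p)
        row["coa_row_px"], row["coa_col_px"] = p.coa
        if areas is not None:
            row["area_um2"] = areas[k]
        rows.append(row)
    return pd.DataFrame(rows)
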