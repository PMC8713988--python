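"""Shared geometric conventions.

Pixel coordinates are (row, col), 0-based, origin at the top-left corner.
Angles are measured in degrees from the image vertical ("up", i.e. the
direction of decreasing row), increasing clockwise in the displayed image
(equivalently counter-clockwise in raw (row, col) axes).  The vertical
diameter of a cell therefore sits at 0 degrees.
"""

from __future__ import annotations

import numpy as np


def unit_direction(angle_deg):
    """Unit vector(s) (d_row, d_col) for angle(s) in degrees.

    0 deg points up (decreasing row); 90 deg points right (increasing col).
    """
    a = np.deg2rad(np.asarray(angle_deg, dtype=float))
    return np.stack([-np.cos(a), np.sin(a)], axis=-1)


def angle_of(vec_rc) -> float:
    """Angle in degrees ([0, 360)) of a (row, col) displacement vector."""
    dr, dc = float(vec_rc[0]), float(vec_rc[1])
    return float(np.degrees(np.arctan2(dc, -dr)) % 360.0)


def shoelace_area(poly: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon given as (N, 2) (row, col)."""
    p = np.asarray(poly, dtype=float)
    r, c = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(c * np.roll(r, -1) - np.roll(c, -1) * r))


def polygon_centroid(poly: np.ndarray) -> np.ndarray:
    """Area centroid (row, col) of a simple polygon (shoelace formula)."""
    p = np.asarray(poly, dtype=float)
    r, c = p[:, 0], p[:, 1]
    r1, c1 = np.roll(r, -1), np.roll(c, -1)
    cross = c * r1 - c1 * r
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        raise ValueError("degenerate polygon: zero area")
    cr = np.sum((r + r1) * cross) / (6.0 * a)
    cc = np.sum((c + c1) * cross) / (6.0 * a)
    return np.array([cr, cc])
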