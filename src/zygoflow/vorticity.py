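"""Vorticity of masked PIV fields and sign-comparison statistics.

Cytoplasmic vortices appear intermittently and the PIV field inside a cell
is rarely complete, so vorticity is estimated pointwise by a least-squares
fit of a local linear velocity model over the valid vectors in each grid
point's 3x3 neighbourhood; the curl is read off the fitted gradients.
Points with fewer than four valid neighbours stay undefined, which is what
makes the estimator tolerant of incomplete vector patterns.  Region series
reduce the defined values inside a cell (or half-cell) mask to a mean
vorticity and a sign per frame pair; signs of two regions are compared per
100-minute window with a chi-squared test on the 2x2 (+, -) count table.

Sign convention: positive vorticity is counter-clockwise in the displayed
image (the curl is evaluated in y-up mathematical axes after flipping the
row axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import chi2_contingency

from .piv import VectorField

__all__ = [
    "VorticitySeries",
    "SignComparison",
    "vorticity_field",
    "region_vorticity_series",
    "split_cell_halves",
    "compare_signs",
]

DEFAULT_NOISE_FLOOR = 0.005   # 1/min; |mean vorticity| below this has sign 0
DEFAULT_MIN_SUPPORT = 4       # defined grid points needed for a usable sign


@dataclass
class VorticitySeries:
    """Per-frame-pair mean vorticity, sign and support for one region."""

    region_id: str
    times: np.ndarray            # minutes, one per frame pair (start frame)
    mean_vorticity: np.ndarray   # 1/min (nan where undefined)
    sign: np.ndarray             # {+1, -1, 0}
    n_valid: np.ndarray          # contributing grid points per frame pair


@dataclass
class SignComparison:
    """Chi-squared comparison of two sign series over one time window."""

    region_pair: Tuple[str, str]
    window: Tuple[float, float]          # [start, end) minutes
    counts: np.ndarray                   # 2x2: rows = regions, cols = (+, -)
    chi_square: float
    p_value: float
    testable: bool
    yates: bool = False


def vorticity_field(field: VectorField, min_neighbours: int = 4) -> np.ndarray:
    """Pointwise vorticity (1/min) of a PIV field; nan where undefined.

    At each grid point a linear velocity model u(x, y), v(x, y) is fitted by
    least squares to the valid vectors of the surrounding 3x3 block (centre
    included); vorticity is dv/dx - du/dy of the fit.  Requires >= 4 valid
    vectors overall, else an empty (all-nan) field is returned.
    """
    if field.valid.sum() < 4:
        return np.full(field.valid.shape, np.nan)
    nr, nc = field.valid.shape
    # y-up physical coordinates in um; u,v in um/min
    x = field.grid_cols * field.pixel_size
    y = -field.grid_rows * field.pixel_size
    s = field.scale_um_min
    u = field.dv_col * s
    v = -field.dv_row * s
    out = np.full((nr, nc), np.nan)
    for i in range(nr):
        for j in range(nc):
            i0, i1 = max(0, i - 1), min(nr, i + 2)
            j0, j1 = max(0, j - 1), min(nc, j + 2)
            sel = field.valid[i0:i1, j0:j1]
            if sel.sum() < min_neighbours:
                continue
            yy, xx = np.meshgrid(y[i0:i1], x[j0:j1], indexing="ij")
            A = np.column_stack([
                np.ones(sel.sum()), xx[sel] - x[j], yy[sel] - y[i]
            ])
            if np.linalg.matrix_rank(A) < 3:
                continue
            coef_u, *_ = np.linalg.lstsq(A, u[i0:i1, j0:j1][sel], rcond=None)
            coef_v, *_ = np.linalg.lstsq(A, v[i0:i1, j0:j1][sel], rcond=None)
            out[i, j] = coef_v[1] - coef_u[2]   # dv/dx - du/dy
    return out


def region_vorticity_series(
    fields: Sequence[VectorField],
    region_masks,
    region_id: str = "cell-1",
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> VorticitySeries:
    """Reduce PIV fields to a per-frame-pair signed vorticity series.

    ``region_masks`` is one bool image per field or a single static mask.
    The sign is 0 when fewer than ``min_support`` grid points are defined in
    the region or when |mean| is below the noise floor.
    """
    single = isinstance(region_masks, np.ndarray) and region_masks.ndim == 2
    times, means, signs, counts = [], [], [], []
    any_nonempty = False
    for k, f in enumerate(fields):
        mask = region_masks if single else region_masks[k]
        vort = vorticity_field(f)
        rr, cc = np.meshgrid(
            f.grid_rows.astype(int), f.grid_cols.astype(int), indexing="ij"
        )
        in_region = mask[rr, cc]
        vals = vort[in_region & np.isfinite(vort)]
        times.append(f.frame_pair[0] * f.frame_interval)
        n = vals.size
        any_nonempty = any_nonempty or in_region.any()
        if n == 0:
            means.append(np.nan)
            signs.append(0)
        else:
            m = float(vals.mean())
            means.append(m)
            signs.append(0 if (n < min_support or abs(m) < noise_floor)
                         else int(np.sign(m)))
        counts.append(n)
    if not any_nonempty:
        raise ValueError(f"region {region_id} empty in all frames")
    return VorticitySeries(
        region_id=region_id,
        times=np.asarray(times, dtype=float),
        mean_vorticity=np.asarray(means, dtype=float),
        sign=np.asarray(signs, dtype=int),
        n_valid=np.asarray(counts, dtype=int),
    )


def split_cell_halves(cell_mask: np.ndarray, axis: Optional[Tuple] = None):
    """Split a cell mask across its longest axis into two half-masks.

    ``axis`` may supply an annotated ((row, col), (row, col)) line, which
    takes precedence; otherwise the maximal-distance chord between convex
    hull points of the mask is used.  The cut is the perpendicular bisector
    of the axis; the halves are disjoint and tile the mask exactly.
    """
    from scipy.spatial import ConvexHull

    mask = np.asarray(cell_mask, dtype=bool)
    pts = np.column_stack(np.nonzero(mask)).astype(float)
    if pts.shape[0] < 4:
        raise ValueError("degenerate cell mask")
    if axis is not None:
        p0, p1 = np.asarray(axis[0], float), np.asarray(axis[1], float)
    else:
        hull_pts = pts[ConvexHull(pts).vertices]
        d2 = np.sum(
            (hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2, axis=-1
        )
        i, j = np.unravel_index(np.argmax(d2), d2.shape)
        p0, p1 = hull_pts[i], hull_pts[j]
    direction = p1 - p0
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        raise ValueError("degenerate axis")
    direction = direction / norm
    mid = 0.5 * (p0 + p1)
    rr, cc = np.meshgrid(
        np.arange(mask.shape[0]), np.arange(mask.shape[1]), indexing="ij"
    )
    proj = (rr - mid[0]) * direction[0] + (cc - mid[1]) * direction[1]
    half_a = mask & (proj < 0)
    half_b = mask & (proj >= 0)
    return half_a, half_b


def _chi2_on_table(table: np.ndarray) -> Tuple[float, float, bool]:
    """Pearson chi-squared (1 df) with Yates' correction when any expected
    count is below 5.  Degenerate tables (a margin of zero) carry no
    association: chi-square 0, p 1."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0, False
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    yates = bool((expected < 5).any())
    res = chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.pvalue), yates


def compare_signs(
    series_a: VorticitySeries,
    series_b: VorticitySeries,
    window: float = 100.0,
    start_time: Optional[float] = None,
    min_count: int = 5,
    method: str = "chi2",
) -> List[SignComparison]:
    """Chi-squared comparison of two sign series in consecutive windows.

    Frame pairs with sign 0 are excluded from the counts.  Windows where
    either region has fewer than ``min_count`` defined signs are reported
    untestable.  ``start_time`` defaults to the start of the overlapping
    time range (in practice: a chosen offset, e.g. 30-99 min after the
    two-indents stage).  ``method="fisher"`` substitutes Fisher's exact
    test for very small counts.
    """
    if method not in ("chi2", "fisher"):
        raise ValueError("method must be 'chi2' or 'fisher'")
    common = np.intersect1d(series_a.times, series_b.times)
    if common.size == 0:
        raise ValueError("sign series share no frame pairs")
    t0 = float(common.min()) if start_time is None else float(start_time)
    t_end = float(common.max())
    comparisons: List[SignComparison] = []
    w0 = t0
    while w0 <= t_end:
        w1 = w0 + window
        sel = (common >= w0) & (common < w1)
        if sel.any():
            ts = common[sel]
            table = np.zeros((2, 2), dtype=int)
            for row, series in enumerate((series_a, series_b)):
                idx = np.isin(series.times, ts)
                s = series.sign[idx]
                table[row, 0] = int((s == 1).sum())
                table[row, 1] = int((s == -1).sum())
            testable = bool((table.sum(axis=1) >= min_count).all())
            if not testable:
                chi2, p, yates = np.nan, np.nan, False
            elif method == "fisher":
                from scipy.stats import fisher_exact

                chi2, yates = np.nan, False
                p = float(fisher_exact(table).pvalue)
            else:
                chi2, p, yates = _chi2_on_table(table)
            comparisons.append(SignComparison(
                region_pair=(series_a.region_id, series_b.region_id),
                window=(w0, w1), counts=table,
                chi_square=chi2, p_value=p, testable=testable, yates=yates,
            ))
        w0 = w1
    if not comparisons:
        raise ValueError("no overlapping defined-sign frames in any window")
    return comparisons
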