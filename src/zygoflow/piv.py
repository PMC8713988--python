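"""Particle image velocimetry by multi-pass normalized cross-correlation.

Square interrogation windows from one frame are matched in the next frame
by normalized cross-correlation (NCC).  Passes successively halve the
window size (default schedule 64 -> 32 px; a 64 -> 16 schedule suits
low-noise footage), each pass shifting the search window by the coarse
displacement interpolated from the previous pass.  Correlation peaks are
located to sub-pixel precision with a three-point Gaussian fit and
validated by the peak-to-second-peak ratio; windows without texture or with
ambiguous peaks yield invalid vectors rather than errors.

Vectors are stored in px/frame; reporting converts to um/min using the
stack calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.interpolate import RegularGridInterpolator

__all__ = ["VectorField", "piv_pair", "piv_stack", "mean_vector",
           "mean_magnitude", "save_quiver_png"]


@dataclass
class VectorField:
    """Displacement vectors on a regular interrogation grid.

    ``dv_row``/``dv_col`` are in px per frame; ``valid`` marks grid points
    whose correlation passed validation (and fell inside any mask).
    """

    grid_rows: np.ndarray        # (nr,) window-centre rows, px
    grid_cols: np.ndarray        # (nc,) window-centre cols, px
    dv_row: np.ndarray           # (nr, nc) px/frame
    dv_col: np.ndarray           # (nr, nc) px/frame
    valid: np.ndarray            # (nr, nc) bool
    frame_pair: Tuple[int, int] = (0, 1)
    window_schedule: Tuple[int, ...] = (64, 32)
    pixel_size: float = 1.0
    frame_interval: float = 1.0

    @property
    def positions(self) -> np.ndarray:
        """(nr, nc, 2) array of window-centre (row, col) coordinates."""
        rr, cc = np.meshgrid(self.grid_rows, self.grid_cols, indexing="ij")
        return np.stack([rr, cc], axis=-1)

    @property
    def scale_um_min(self) -> float:
        return self.pixel_size / self.frame_interval

    def vectors_um_min(self) -> np.ndarray:
        """(nr, nc, 2) displacement in um/min (invalid entries are nan)."""
        v = np.stack([self.dv_row, self.dv_col], axis=-1) * self.scale_um_min
        v[~self.valid] = np.nan
        return v

    def speed_um_min(self) -> np.ndarray:
        v = self.vectors_um_min()
        return np.hypot(v[..., 0], v[..., 1])


def _subpixel_offset(c_minus, c0, c_plus):
    """Vectorized three-point Gaussian peak fit (parabolic fallback when a
    lobe is non-positive); returns the fractional offset in [-1, 1]."""
    c_minus, c0, c_plus = (np.asarray(x, dtype=float) for x in (c_minus, c0, c_plus))
    positive = (c_minus > 0) & (c0 > 0) & (c_plus > 0)
    lm = np.where(positive, np.log(np.clip(c_minus, 1e-300, None)), c_minus)
    l0 = np.where(positive, np.log(np.clip(c0, 1e-300, None)), c0)
    lp = np.where(positive, np.log(np.clip(c_plus, 1e-300, None)), c_plus)
    denom = lm + lp - 2.0 * l0
    with np.errstate(divide="ignore", invalid="ignore"):
        off = 0.5 * (lm - lp) / denom
    off = np.where(np.abs(denom) < 1e-12, 0.0, off)
    return np.clip(np.nan_to_num(off), -1.0, 1.0)


def _window_sums(reg: np.ndarray, w: int):
    """Sums of all w x w windows of each (S, S) region via integral images."""
    n, S, _ = reg.shape
    ii = np.zeros((n, S + 1, S + 1))
    ii[:, 1:, 1:] = reg.cumsum(axis=1).cumsum(axis=2)
    return ii[:, w:, w:] - ii[:, :-w, w:] - ii[:, w:, :-w] + ii[:, :-w, :-w]


def _correlate_batch(a, b, rows, cols, half, margin, shift_r, shift_c, peak_ratio):
    """Batched NCC of interrogation windows.

    ``rows``/``cols`` are the window centres (int arrays, N), ``shift_r``/
    ``shift_c`` integer search-window offsets from the coarse pass.  Search
    regions are clamped inside the image.  Returns (dv_r, dv_c, ok), each N.
    """
    H, W = a.shape
    w = 2 * half
    S = w + 2 * margin
    K = 2 * margin + 1
    N = rows.size
    dv_r = np.zeros(N)
    dv_c = np.zeros(N)
    ok = np.zeros(N, dtype=bool)
    if N == 0 or S > min(H, W):
        return dv_r, dv_c, ok
    offs_t = np.arange(-half, half)
    offs_s = np.arange(S)
    r0_nom = rows + shift_r - half - margin
    c0_nom = cols + shift_c - half - margin
    r0 = np.clip(r0_nom, 0, H - S)
    c0 = np.clip(c0_nom, 0, W - S)
    # a clamped search region cannot cover the symmetric search range, so
    # any peak it yields is unreliable
    complete = (r0 == r0_nom) & (c0 == c0_nom)

    # chunk to bound memory (regions + their FFTs dominate)
    chunk = max(1, int(4e6 / (S * S)))
    n2 = float(w * w)
    for lo in range(0, N, chunk):
        hi = min(N, lo + chunk)
        rr, cc = rows[lo:hi], cols[lo:hi]
        tpl = a[rr[:, None, None] + offs_t[None, :, None],
                cc[:, None, None] + offs_t[None, None, :]]
        tpl = tpl - tpl.mean(axis=(1, 2), keepdims=True)
        tnorm = np.sqrt((tpl**2).sum(axis=(1, 2)))
        reg = b[r0[lo:hi, None, None] + offs_s[None, :, None],
                c0[lo:hi, None, None] + offs_s[None, None, :]]
        F = np.fft.rfft2(reg)
        T = np.fft.rfft2(tpl[:, ::-1, ::-1], s=(S, S))
        corr = np.fft.irfft2(F * T, s=(S, S))[:, w - 1:, w - 1:]
        lsum = _window_sums(reg, w)
        lsum2 = _window_sums(reg**2, w)
        var = np.clip(lsum2 - lsum**2 / n2, 0.0, None)
        denom = tnorm[:, None, None] * np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            ncc = np.where(denom > 1e-9, corr / denom, 0.0)
        ncc = np.clip(np.nan_to_num(ncc), -1.1, 1.1)

        m = hi - lo
        flat = ncc.reshape(m, -1)
        idx = flat.argmax(axis=1)
        pr, pc = np.divmod(idx, K)
        peak = flat[np.arange(m), idx]
        good = (tnorm > 1e-7 * n2) & (peak > 0) & complete[lo:hi]
        # a peak on the search-domain border cannot be trusted (the true
        # match may lie outside, e.g. when the region was clamped at the
        # image edge) and admits no sub-pixel fit
        good &= (pr > 0) & (pr < K - 1) & (pc > 0) & (pc < K - 1)
        # peak-to-second-peak ratio, excluding the 3x3 around the peak
        for k in np.nonzero(good)[0]:
            sub = ncc[k].copy()
            sub[max(0, pr[k] - 1):pr[k] + 2, max(0, pc[k] - 1):pc[k] + 2] = -np.inf
            second = sub.max()
            if np.isfinite(second) and second > 0 and peak[k] / second < peak_ratio:
                good[k] = False
        # sub-pixel refinement where the peak is interior
        fr = pr.astype(float)
        fc = pc.astype(float)
        inner_r = (pr > 0) & (pr < K - 1)
        inner_c = (pc > 0) & (pc < K - 1)
        kk = np.arange(m)
        fr[inner_r] += _subpixel_offset(
            ncc[kk[inner_r], pr[inner_r] - 1, pc[inner_r]],
            peak[inner_r],
            ncc[kk[inner_r], pr[inner_r] + 1, pc[inner_r]],
        )
        fc[inner_c] += _subpixel_offset(
            ncc[kk[inner_c], pr[inner_c], pc[inner_c] - 1],
            peak[inner_c],
            ncc[kk[inner_c], pr[inner_c], pc[inner_c] + 1],
        )
        dv_r[lo:hi] = r0[lo:hi] + fr - (rr - half)
        dv_c[lo:hi] = c0[lo:hi] + fc - (cc - half)
        ok[lo:hi] = good
    return dv_r, dv_c, ok


def _window_schedule(initial: int, final: int) -> Tuple[int, ...]:
    sched = [int(initial)]
    while sched[-1] > final:
        sched.append(max(int(final), sched[-1] // 2))
    return tuple(sched)


def piv_pair(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    initial_window: int = 64,
    final_window: int = 32,
    overlap: float = 0.5,
    mask: Optional[np.ndarray] = None,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
    peak_ratio: float = 1.2,
    frame_pair: Tuple[int, int] = (0, 1),
) -> VectorField:
    """Estimate the displacement field from ``frame_a`` to ``frame_b``.

    ``mask`` (optional bool image) restricts vectors to window centres
    inside it, e.g. the tracked cell interior.  Displacements beyond half
    the initial window are rejected as out of search range.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must share a shape")
    if not (8 <= final_window <= initial_window):
        raise ValueError("need 8 <= final_window <= initial_window")
    H, W = a.shape
    schedule = _window_schedule(initial_window, final_window)
    max_disp = initial_window / 2.0

    coarse = None  # (rows, cols, dv_r 2-D, dv_c 2-D) of the previous pass
    field = None
    for w in schedule:
        half = w // 2
        margin = half
        step = max(4, int(round(w * (1.0 - overlap))))
        rows = np.arange(half, H - half + 1, step)
        cols = np.arange(half, W - half + 1, step)
        nr, nc = rows.size, cols.size
        dv_r = np.zeros((nr, nc))
        dv_c = np.zeros((nr, nc))
        ok = np.zeros((nr, nc), dtype=bool)
        if coarse is not None:
            pts = np.stack(np.meshgrid(rows, cols, indexing="ij"), axis=-1)
            shift_r = coarse[0](pts.reshape(-1, 2)).reshape(nr, nc)
            shift_c = coarse[1](pts.reshape(-1, 2)).reshape(nr, nc)
        else:
            shift_r = np.zeros((nr, nc))
            shift_c = np.zeros((nr, nc))
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        if mask is not None:
            active = mask[rr, cc].ravel()
        else:
            active = np.ones(nr * nc, dtype=bool)
        sel = np.nonzero(active)[0]
        bdr, bdc, bok = _correlate_batch(
            a, b, rr.ravel()[sel], cc.ravel()[sel], half, margin,
            np.round(shift_r.ravel()[sel]).astype(int),
            np.round(shift_c.ravel()[sel]).astype(int), peak_ratio,
        )
        bok &= np.hypot(bdr, bdc) <= max_disp
        dv_r.ravel()[sel] = np.where(bok, bdr, 0.0)
        dv_c.ravel()[sel] = np.where(bok, bdc, 0.0)
        ok.ravel()[sel] = bok
        field = VectorField(
            grid_rows=rows.astype(float), grid_cols=cols.astype(float),
            dv_row=dv_r, dv_col=dv_c, valid=ok,
            frame_pair=frame_pair, window_schedule=schedule,
            pixel_size=pixel_size, frame_interval=frame_interval,
        )
        if w != schedule[-1]:
            coarse = _coarse_interpolators(field)
    return field


def _coarse_interpolators(field: VectorField):
    """Bilinear interpolators of the (gap-filled) coarse displacement field."""
    dv_r = field.dv_row.copy()
    dv_c = field.dv_col.copy()
    if field.valid.any():
        dv_r[~field.valid] = dv_r[field.valid].mean()
        dv_c[~field.valid] = dv_c[field.valid].mean()
    else:
        dv_r[:] = 0.0
        dv_c[:] = 0.0
    kw = dict(bounds_error=False, fill_value=None, method="linear")
    return (
        RegularGridInterpolator((field.grid_rows, field.grid_cols), dv_r, **kw),
        RegularGridInterpolator((field.grid_rows, field.grid_cols), dv_c, **kw),
    )


def piv_stack(stack, mask=None, masks=None, **kwargs):
    """PIV over all consecutive frame pairs of a stack.

    ``mask`` applies to every pair; ``masks`` (sequence, one per pair)
    overrides it.  Returns a list of :class:`VectorField`.
    """
    fields = []
    for i in range(len(stack) - 1):
        m = masks[i] if masks is not None else mask
        fields.append(piv_pair(
            stack.frames[i], stack.frames[i + 1],
            mask=m,
            pixel_size=stack.pixel_size, frame_interval=stack.frame_interval,
            frame_pair=(i, i + 1), **kwargs,
        ))
    return fields


def _region_selector(field: VectorField, region) -> np.ndarray:
    """Boolean grid selection for an Outline, a mask image, or None."""
    if region is None:
        return np.ones_like(field.valid, dtype=bool)
    if isinstance(region, np.ndarray) and region.dtype == bool:
        rr, cc = np.meshgrid(
            field.grid_rows.astype(int), field.grid_cols.astype(int), indexing="ij"
        )
        return region[rr, cc]
    boundary = getattr(region, "boundary", None)
    if boundary is not None:
        path = MplPath(np.column_stack([boundary[:, 1], boundary[:, 0]]))
        pts = field.positions.reshape(-1, 2)
        inside = path.contains_points(np.column_stack([pts[:, 1], pts[:, 0]]))
        return inside.reshape(field.valid.shape)
    raise TypeError("region must be None, a bool mask image, or an Outline")


def mean_vector(field: VectorField, region=None) -> np.ndarray:
    """Arithmetic mean (v_row, v_col) in um/min of valid vectors in a region."""
    sel = field.valid & _region_selector(field, region)
    if not sel.any():
        raise ValueError("no valid vectors in region")
    s = field.scale_um_min
    return np.array([field.dv_row[sel].mean() * s, field.dv_col[sel].mean() * s])


def save_quiver_png(field: VectorField, frame: np.ndarray, path,
                    region=None, arrow_scale: float = 4.0) -> None:
    """Render the frame with vector arrows (and the red mean vector) to PNG.

    The figure is rasterized to an array and written with imageio, so the
    bytes are deterministic across reruns.
    """
    import imageio.v3 as iio
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    fig = Figure(figsize=(6, 6), dpi=100)
    canvas = FigureCanvasAgg(fig)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.imshow(frame, cmap="gray", interpolation="nearest")
    rr, cc = np.meshgrid(field.grid_rows, field.grid_cols, indexing="ij")
    sel = field.valid
    ax.quiver(cc[sel], rr[sel],
              field.dv_col[sel] * arrow_scale, field.dv_row[sel] * arrow_scale,
              angles="xy", scale_units="xy", scale=1.0,
              color="k", width=0.003)
    try:
        mv = mean_vector(field, region) / field.scale_um_min  # back to px/frame
        centre = (float(np.mean(field.grid_cols[sel.any(axis=0)])),
                  float(np.mean(field.grid_rows[sel.any(axis=1)])))
        ax.quiver([centre[0]], [centre[1]],
                  [mv[1] * arrow_scale * 4], [mv[0] * arrow_scale * 4],
                  angles="xy", scale_units="xy", scale=1.0,
                  color="r", width=0.006)
    except ValueError:
        pass
    ax.set_axis_off()
    canvas.draw()
    img = np.asarray(canvas.buffer_rgba())[..., :3]
    iio.imwrite(path, img)


def mean_magnitude(field: VectorField, rect: Sequence[float]) -> float:
    """Mean speed (um/min) of valid vectors inside a (rmin, rmax, cmin, cmax)
    pixel rectangle — the cytoplasmic-speed readout."""
    rmin, rmax, cmin, cmax = rect
    rr, cc = np.meshgrid(field.grid_rows, field.grid_cols, indexing="ij")
    sel = field.valid & (rr >= rmin) & (rr <= rmax) & (cc >= cmin) & (cc <= cmax)
    if not sel.any():
        raise ValueError("rectangle contains no valid vectors")
    speed = np.hypot(field.dv_row, field.dv_col) * field.scale_um_min
    return float(speed[sel].mean())
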