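"""Space-time intensity images along a chosen diameter.

A kymograph samples the stack intensity along one line per frame and
stacks the samples as columns: rows are positions along the line (1 px
steps, reported in um), columns are frames.  The line is a diameter at a
fixed angle, anchored either at the per-frame CoA (so it tracks the cell)
or at a fixed point (for zona-referenced views); an end-window mode keeps
only a sub-segment at one end of the diameter, where membrane-zona contact
dynamics are most visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from ._geom import unit_direction

__all__ = ["Kymograph", "extract_kymograph", "kymograph_to_png"]


@dataclass
class Kymograph:
    """Space-time image: rows = positions along the line, cols = frames."""

    image: np.ndarray
    angle: float                 # degrees from vertical
    length_um: float
    positions_um: np.ndarray     # (rows,) signed position along the line
    anchor_mode: str             # "coa" or "fixed"
    pixel_size: float
    frame_interval: float


def extract_kymograph(
    stack,
    angle: float,
    length_um: float,
    anchor="coa",
    outlines: Optional[Sequence] = None,
    segment: str = "full",
    segment_um: Optional[float] = None,
) -> Kymograph:
    """Sample a diameter line across all frames of a stack.

    Parameters
    ----------
    angle
        Line angle in degrees from the image vertical.
    length_um
        Total line length in um, centred on the anchor.
    anchor
        ``"coa"`` (requires ``outlines``, one per frame) anchors the line at
        each frame's centre of area; a (row, col) point fixes it.
    segment, segment_um
        ``"end"`` keeps only the trailing ``segment_um`` of the line (the
        end the angle points away from, i.e. the "bottom" end for 0 deg).
    """
    n_px = int(round(length_um / stack.pixel_size))
    if n_px < 2:
        raise ValueError("line shorter than 2 px")
    offsets = np.arange(n_px, dtype=float) - (n_px - 1) / 2.0
    d = unit_direction(angle)
    H, W = stack.shape
    columns = []
    for i, frame in enumerate(stack.frames):
        if isinstance(anchor, str) and anchor == "coa":
            if outlines is None:
                raise ValueError("CoA anchoring requires outlines")
            centre = np.asarray(outlines[i].centre, dtype=float)
        else:
            centre = np.asarray(anchor, dtype=float)
        rows = centre[0] + offsets * d[0]
        cols = centre[1] + offsets * d[1]
        if rows.min() < 0 or rows.max() > H - 1 or cols.min() < 0 or cols.max() > W - 1:
            raise ValueError(f"line exits the image in frame {i}")
        columns.append(map_coordinates(frame, [rows, cols], order=1))
    image = np.column_stack(columns)
    positions = offsets * stack.pixel_size
    if segment == "end":
        if not segment_um or segment_um <= 0:
            raise ValueError("end-window mode needs a positive segment_um")
        keep = int(round(segment_um / stack.pixel_size))
        image = image[-keep:]
        positions = positions[-keep:]
    elif segment != "full":
        raise ValueError("segment must be 'full' or 'end'")
    return Kymograph(
        image=image, angle=float(angle), length_um=float(length_um),
        positions_um=positions,
        anchor_mode="coa" if (isinstance(anchor, str) and anchor == "coa") else "fixed",
        pixel_size=stack.pixel_size, frame_interval=stack.frame_interval,
    )


def kymograph_to_png(kymo: Kymograph, path) -> None:
    """Write the kymograph as an 8-bit grayscale PNG (deterministic bytes)."""
    import imageio.v3 as iio

    img = kymo.image
    lo, hi = float(img.min()), float(img.max())
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    iio.imwrite(path, ((img - lo) * scale).astype(np.uint8))
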