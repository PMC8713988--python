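"""Synthetic zygote time-lapse generator with full ground truth.

Renders calibrated grayscale stacks that emulate the structures the
analysis pipeline measures: a textured cell (circle or ellipse) inside a
static, slightly elliptical zona-pellucida ring; per-diameter shape
modulation cycles; a cytokinesis script (elongation ramp, slimming and
deepening furrow indents); and internal flow (translation, solid-body
rotation, or vortex pairs) that advects the granule texture between frames
by backward bilinear warping.  Every stack comes with ground truth —
per-frame boundary polygons and masks per cell, the analytic flow field,
and the injected shape-event list — so each analysis stage can be tested
against known answers.

Everything is deterministic given the texture/noise seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.draw import polygon2mask

from ._geom import unit_direction
from .io import FrameStack

__all__ = [
    "DiameterCycle",
    "FlowSpec",
    "CytokinesisScript",
    "CellGeometry",
    "ScenarioSpec",
    "GroundTruth",
    "render_scenario",
    "preset_library",
    "get_preset",
]


@dataclass
class DiameterCycle:
    """An injected in-out-in cycle of one diameter.

    The diameter at ``angle_deg`` rises by ``amplitude_um`` from frame
    ``t_start`` to the cycle midpoint and falls back by ``t_end``
    (half-sine time course, cosine-squared angular bump of half-width
    ``width_deg`` applied to both opposed radii).
    """

    angle_deg: float
    amplitude_um: float
    t_start: int
    t_end: int
    width_deg: float = 30.0

    @property
    def t_peak(self) -> int:
        return (self.t_start + self.t_end) // 2


@dataclass
class FlowSpec:
    """Internal flow model.

    kind: "none" | "translation" | "solid_rotation" | "vortex_pair".
    ``velocity_um_min`` (row, col) for translation; ``vortices`` is a list
    of (centre_px (row, col), omega_rad_min, core_radius_px) — positive
    omega is counter-clockwise in the displayed image.  ``t_start``/
    ``t_end`` window the flow in frames (None = always on).
    """

    kind: str = "none"
    velocity_um_min: Tuple[float, float] = (0.0, 0.0)
    vortices: Sequence[Tuple] = ()
    t_start: Optional[int] = None
    t_end: Optional[int] = None
    confine_to_cells: bool = False   # vortex i acts only inside cell i

    def active(self, t: int) -> bool:
        if self.kind == "none":
            return False
        lo = -np.inf if self.t_start is None else self.t_start
        hi = np.inf if self.t_end is None else self.t_end
        return lo <= t < hi


@dataclass
class CytokinesisScript:
    """Elongation/indentation of the dividing cell.

    Between ``t_start`` and ``t_end`` the axis diameter extends linearly by
    ``extension_um`` while the perpendicular slims by ``slimming_um``;
    furrow indents (Gaussian dips of ``indent_depth_um``, angular sigma
    ``indent_sigma_deg``) deepen from ``indent_start`` on, the second one
    ``indent_stagger`` frames after the first.
    """

    t_start: int
    t_end: int
    axis_deg: float
    extension_um: float
    slimming_um: float = 0.0
    indent_depth_um: float = 0.0
    indent_start: Optional[int] = None
    indent_stagger: int = 0
    indent_sigma_deg: float = 14.0


@dataclass
class CellGeometry:
    """Base geometry of one cell: a circle or an oriented ellipse."""

    centre_px: Tuple[float, float]
    base_radius_um: Optional[float] = None
    semi_axes_um: Optional[Tuple[float, float]] = None   # (along axis, perp)
    orientation_deg: float = 0.0


@dataclass
class ScenarioSpec:
    """Complete description of a synthetic recording."""

    shape: Tuple[int, int] = (256, 256)
    pixel_size: float = 0.5          # um/px
    frame_interval: float = 2.0      # min
    n_frames: int = 30
    cells: List[CellGeometry] = field(default_factory=list)
    cycles: List[DiameterCycle] = field(default_factory=list)
    cytokinesis: Optional[CytokinesisScript] = None
    flow: FlowSpec = field(default_factory=FlowSpec)
    zona: Optional[dict] = None      # {inner_um, outer_um, axis_ratio, orientation_deg}
    n_granules: int = 350
    granule_sigma_px: float = 1.6
    granule_contrast: float = 0.18
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not self.cells:
            centre = (self.shape[0] / 2.0, self.shape[1] / 2.0)
            self.cells = [CellGeometry(centre_px=centre, base_radius_um=35.0)]


# ---------------------------------------------------------------------------
# geometry evaluation

def _ellipse_radius(theta_deg, a, b, orientation_deg):
    d = np.deg2rad(np.asarray(theta_deg) - orientation_deg)
    return a * b / np.sqrt((b * np.cos(d)) ** 2 + (a * np.sin(d)) ** 2)


def _angular_distance(theta_deg, centre_deg):
    return np.abs((np.asarray(theta_deg) - centre_deg + 180.0) % 360.0 - 180.0)


def _radius_px(spec: ScenarioSpec, cell: CellGeometry, theta_deg, t: int):
    """Cell boundary radius (px) at angle(s) theta for frame t."""
    px = spec.pixel_size
    if cell.semi_axes_um is not None:
        a, b = cell.semi_axes_um
        r = _ellipse_radius(theta_deg, a / px, b / px, cell.orientation_deg)
    else:
        r = np.full_like(np.asarray(theta_deg, dtype=float),
                         cell.base_radius_um / px)
    for cyc in spec.cycles:
        if cyc.t_start <= t <= cyc.t_end:
            s = np.sin(np.pi * (t - cyc.t_start) / (cyc.t_end - cyc.t_start))
            for ang in (cyc.angle_deg, cyc.angle_deg + 180.0):
                dist = _angular_distance(theta_deg, ang)
                bump = np.where(
                    dist < cyc.width_deg,
                    np.cos(np.pi * dist / (2.0 * cyc.width_deg)) ** 2, 0.0,
                )
                r = r + 0.5 * (cyc.amplitude_um / px) * s * bump
    ck = spec.cytokinesis
    if ck is not None and t >= ck.t_start:
        e = min(1.0, (t - ck.t_start) / max(1, ck.t_end - ck.t_start))
        d_ax = np.deg2rad(np.asarray(theta_deg) - ck.axis_deg)
        r = r + 0.5 * (ck.extension_um / px) * e * np.cos(d_ax) ** 2
        r = r - 0.5 * (ck.slimming_um / px) * e * np.sin(d_ax) ** 2
        if ck.indent_depth_um and ck.indent_start is not None:
            for k, ang in enumerate((ck.axis_deg + 90.0, ck.axis_deg - 90.0)):
                start = ck.indent_start + k * ck.indent_stagger
                if t >= start:
                    depth = min(1.0, (t - start + 1) / max(1, ck.t_end - start))
                    dist = _angular_distance(theta_deg, ang)
                    r = r - (ck.indent_depth_um / px) * depth * np.exp(
                        -0.5 * (dist / ck.indent_sigma_deg) ** 2
                    )
    return r


def _cell_polygon(spec, cell, t, n_angles=360):
    theta = np.arange(n_angles) * (360.0 / n_angles)
    r = _radius_px(spec, cell, theta, t)
    d = unit_direction(theta)
    return np.asarray(cell.centre_px, dtype=float) + d * r[:, None]


# ---------------------------------------------------------------------------
# flow evaluation

def _velocity_px_frame(spec: ScenarioSpec, rows, cols, t: int):
    """Displacement (px/frame) of the flow model at positions for step t->t+1."""
    dvr = np.zeros_like(np.asarray(rows, dtype=float))
    dvc = np.zeros_like(dvr)
    fl = spec.flow
    if not fl.active(t):
        return dvr, dvc
    scale = spec.frame_interval / spec.pixel_size   # um/min -> px/frame
    if fl.kind == "translation":
        dvr += fl.velocity_um_min[0] * scale
        dvc += fl.velocity_um_min[1] * scale
    elif fl.kind in ("solid_rotation", "vortex_pair"):
        for k, (centre, omega, core) in enumerate(fl.vortices):
            phi = omega * spec.frame_interval     # rad/frame
            rr = np.asarray(rows, dtype=float) - centre[0]
            cc = np.asarray(cols, dtype=float) - centre[1]
            rho = np.hypot(rr, cc)
            if fl.confine_to_cells:
                # rigid rotation of the whole cytoplasm, cut off at the
                # membrane of the associated cell (3 px soft edge)
                cell = spec.cells[min(k, len(spec.cells) - 1)]
                theta = np.degrees(np.arctan2(
                    np.asarray(cols, dtype=float) - cell.centre_px[1],
                    -(np.asarray(rows, dtype=float) - cell.centre_px[0]),
                ))
                r_b = _radius_px(spec, cell, theta, t)
                rho_c = np.hypot(np.asarray(rows, float) - cell.centre_px[0],
                                 np.asarray(cols, float) - cell.centre_px[1])
                taper = _smoothstep((r_b - rho_c) / 3.0)
            else:
                # free vortex: solid body inside 0.8*core, linear taper to
                # zero at the core edge
                taper = np.clip((core - rho) / (0.2 * core), 0.0, 1.0)
            dvr += -phi * cc * taper
            dvc += phi * rr * taper
    else:
        raise ValueError(f"unknown flow kind {fl.kind!r}")
    return dvr, dvc


# ---------------------------------------------------------------------------
# ground truth container

@dataclass
class GroundTruth:
    """Analytic truth accompanying a rendered stack."""

    spec: ScenarioSpec
    outlines: List[List[np.ndarray]]     # [frame][cell] -> (360, 2) polygon px
    cell_masks: List[List[np.ndarray]]   # [frame][cell] -> bool image
    events: List[dict]                   # injected shape cycles
    vortex_signs: List[int]              # per cell, sign of injected vorticity

    def velocity_px_frame(self, rows, cols, t: int):
        """Analytic flow displacement (px/frame) at arbitrary positions."""
        return _velocity_px_frame(self.spec, rows, cols, t)

    def flow_at_grid(self, grid_rows, grid_cols, t: int):
        rr, cc = np.meshgrid(grid_rows, grid_cols, indexing="ij")
        return self.velocity_px_frame(rr, cc, t)


# ---------------------------------------------------------------------------
# rendering

def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def render_scenario(spec: ScenarioSpec):
    """Render a scenario into a calibrated stack plus its ground truth.

    Texture inside the cells is advected frame-to-frame by the flow model
    (backward bilinear warping), the boundary is drawn as a dark membrane
    rim (a strong intensity edge), and Gaussian read noise is added last.
    """
    H, W = spec.shape
    rng = np.random.default_rng(spec.seed)
    rows, cols = np.meshgrid(np.arange(H, dtype=float),
                             np.arange(W, dtype=float), indexing="ij")

    # static granule texture canvas, advected in place by the flow
    tex = np.full((H, W), 0.55)
    extent = max(
        (max(c.semi_axes_um) if c.semi_axes_um else c.base_radius_um)
        for c in spec.cells
    ) / spec.pixel_size
    for cell in spec.cells:
        n = spec.n_granules // len(spec.cells)
        rho = extent * np.sqrt(rng.random(n))
        ang = 2 * np.pi * rng.random(n)
        gr = cell.centre_px[0] + rho * np.cos(ang)
        gc = cell.centre_px[1] + rho * np.sin(ang)
        amp = spec.granule_contrast * rng.choice([-1.0, 1.0], n)
        for yy, xx, aa in zip(gr, gc, amp):
            r0, r1 = int(max(0, yy - 4)), int(min(H, yy + 5))
            c0, c1 = int(max(0, xx - 4)), int(min(W, xx + 5))
            if r1 <= r0 or c1 <= c0:
                continue
            blob = np.exp(
                -((rows[r0:r1, c0:c1] - yy) ** 2 + (cols[r0:r1, c0:c1] - xx) ** 2)
                / (2 * spec.granule_sigma_px ** 2)
            )
            tex[r0:r1, c0:c1] += aa * blob
    tex = np.clip(tex, 0.05, 1.0)

    # static zona ring about the image centre
    zona_dark = np.zeros((H, W))
    if spec.zona:
        z = spec.zona
        ratio = z.get("axis_ratio", 1.0)
        orient = z.get("orientation_deg", 0.0)
        zc = z.get("centre_px", (H / 2.0, W / 2.0))
        rr, cc = rows - zc[0], cols - zc[1]
        theta = np.degrees(np.arctan2(cc, -rr))
        rho = np.hypot(rr, cc)
        r_in = _ellipse_radius(theta, z["inner_um"] * np.sqrt(ratio),
                               z["inner_um"] / np.sqrt(ratio), orient) / spec.pixel_size
        r_out = _ellipse_radius(theta, z["outer_um"] * np.sqrt(ratio),
                                z["outer_um"] / np.sqrt(ratio), orient) / spec.pixel_size
        zona_dark = _smoothstep(rho - r_in + 1.0) * _smoothstep(r_out - rho + 1.0)

    # cumulative flow maps (per-vortex rotation-angle fields and a global
    # translation offset): each frame's texture is sampled from the initial
    # canvas in one interpolation, so repeated warping never blurs it away
    fl = spec.flow
    taper_fields = []
    if fl.kind in ("solid_rotation", "vortex_pair"):
        for k, (centre, _omega, core) in enumerate(fl.vortices):
            rr0 = rows - centre[0]
            cc0 = cols - centre[1]
            rho = np.hypot(rr0, cc0)
            if fl.confine_to_cells:
                cell = spec.cells[min(k, len(spec.cells) - 1)]
                theta = np.degrees(np.arctan2(cols - cell.centre_px[1],
                                              -(rows - cell.centre_px[0])))
                r_b = _radius_px(spec, cell, theta, 0)
                rho_c = np.hypot(rows - cell.centre_px[0],
                                 cols - cell.centre_px[1])
                taper_fields.append(_smoothstep((r_b - rho_c) / 3.0))
            else:
                taper_fields.append(np.clip((core - rho) / (0.2 * core), 0.0, 1.0))
    cum_phi = np.zeros(max(1, len(fl.vortices)))
    cum_off = np.zeros(2)

    frames = np.empty((spec.n_frames, H, W))
    tex0 = tex
    outlines: List[List[np.ndarray]] = []
    masks: List[List[np.ndarray]] = []
    for t in range(spec.n_frames):
        if t > 0 and fl.active(t - 1):
            scale = spec.frame_interval / spec.pixel_size
            if fl.kind == "translation":
                cum_off += np.array(fl.velocity_um_min) * scale
            else:
                for k, (_c, omega, _core) in enumerate(fl.vortices):
                    cum_phi[k] += omega * spec.frame_interval
        if cum_phi.any() or cum_off.any():
            src_r = rows - cum_off[0]
            src_c = cols - cum_off[1]
            for k, tf in enumerate(taper_fields):
                centre = fl.vortices[k][0]
                ang = cum_phi[k] * tf
                ca, sa = np.cos(ang), np.sin(ang)
                dr = src_r - centre[0]
                dc = src_c - centre[1]
                # inverse rotation (negative cumulative angle)
                src_r = centre[0] + ca * dr + sa * dc
                src_c = centre[1] - sa * dr + ca * dc
            tex = map_coordinates(tex0, [src_r, src_c], order=1, mode="reflect")
        else:
            tex = tex0
        img = np.full((H, W), 0.40)
        img -= 0.18 * zona_dark
        frame_outlines, frame_masks = [], []
        for cell in spec.cells:
            theta = np.degrees(np.arctan2(cols - cell.centre_px[1],
                                          -(rows - cell.centre_px[0])))
            rho = np.hypot(rows - cell.centre_px[0], cols - cell.centre_px[1])
            r_b = _radius_px(spec, cell, theta, t)
            # intensity step centred on the true boundary (the Sobel
            # maximum then sits on r_b), plus a faint membrane line
            blend = _smoothstep((r_b - rho) / 1.0 + 0.5)
            img = img * (1.0 - blend) + tex * blend
            rim = np.exp(-0.5 * ((rho - r_b) / 1.2) ** 2)
            img -= 0.08 * rim
            poly = _cell_polygon(spec, cell, t)
            frame_outlines.append(poly)
            frame_masks.append(polygon2mask((H, W), poly))
        outlines.append(frame_outlines)
        masks.append(frame_masks)
        img += rng.normal(0.0, spec.noise_sd, size=(H, W))
        frames[t] = np.clip(img, 0.0, 1.0)

    events = [
        {
            "kind": "shape_sequence",
            "angle_deg": c.angle_deg % 180.0,
            "start_frame": c.t_start,
            "peak_frame": c.t_peak,
            "end_frame": c.t_end,
            "amplitude_um": c.amplitude_um,
        }
        for c in spec.cycles
    ]
    signs = []
    fl = spec.flow
    for cell in spec.cells:
        s = 0
        if fl.kind in ("solid_rotation", "vortex_pair"):
            best, bestd = 0, np.inf
            for centre, omega, _core in fl.vortices:
                d = np.hypot(centre[0] - cell.centre_px[0],
                             centre[1] - cell.centre_px[1])
                if d < bestd:
                    best, bestd = int(np.sign(omega)), d
            s = best
        signs.append(s)

    stack = FrameStack(frames=frames, pixel_size=spec.pixel_size,
                       frame_interval=spec.frame_interval)
    truth = GroundTruth(spec=spec, outlines=outlines, cell_masks=masks,
                        events=events, vortex_signs=signs)
    return stack, truth


# ---------------------------------------------------------------------------
# presets

def _two_cell_spec(n_frames: int, frame_interval: float, omega: float,
                   seed: int) -> ScenarioSpec:
    c1, c2 = (128.0, 90.0), (128.0, 166.0)
    return ScenarioSpec(
        shape=(256, 256), pixel_size=0.5, frame_interval=frame_interval,
        n_frames=n_frames,
        cells=[
            CellGeometry(centre_px=c1, semi_axes_um=(25.0, 18.0)),
            CellGeometry(centre_px=c2, semi_axes_um=(25.0, 18.0)),
        ],
        flow=FlowSpec(kind="vortex_pair", confine_to_cells=True,
                      vortices=[(c1, omega, 50.0), (c2, -omega, 50.0)]),
        zona={"inner_um": 58.0, "outer_um": 62.0, "axis_ratio": 1.05},
        n_granules=700, noise_sd=0.008, seed=seed,
    )


def preset_library(seed: int = 0) -> Dict[str, ScenarioSpec]:
    """Named scenarios covering the phenomena the pipeline measures."""
    centre = (128.0, 128.0)
    return {
        # repeated rounder-distorted-rounder cycles during interphase
        "interphase_cycles": ScenarioSpec(
            n_frames=60,
            cells=[CellGeometry(centre_px=centre, base_radius_um=35.0)],
            cycles=[
                DiameterCycle(140.0, 3.5, 5, 25),
                DiameterCycle(40.0, 4.0, 32, 52),
            ],
            zona={"inner_um": 44.0, "outer_um": 49.0, "axis_ratio": 1.07},
            seed=seed,
        ),
        # brief cytoplasmic speed spike around pronuclear envelope breakdown
        "pnebd_burst": ScenarioSpec(
            n_frames=40,
            cells=[CellGeometry(centre_px=centre, base_radius_um=35.0)],
            flow=FlowSpec(kind="solid_rotation", confine_to_cells=True,
                          vortices=[(centre, 0.03, 64.0)],
                          t_start=18, t_end=25),
            zona={"inner_um": 44.0, "outer_um": 49.0, "axis_ratio": 1.07},
            seed=seed,
        ),
        # nascent two-cell stage with mirrored counter-rotating vortices
        "cytokinesis_vortices": _two_cell_spec(61, 2.0, 0.02, seed),
        # signed vorticity persisting > 550 min of simulated time
        "two_cell_persistence": _two_cell_spec(112, 5.0, 0.012, seed),
    }


def get_preset(name: str, seed: int = 0, **overrides) -> ScenarioSpec:
    """Fetch a preset spec by name, optionally overriding fields."""
    lib = preset_library(seed=seed)
    if name not in lib:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(lib)}")
    spec = lib[name]
    return replace(spec, **overrides) if overrides else spec
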