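"""End-to-end orchestration: outline -> morphometrics -> sequences -> PIV ->
vorticity -> reports.

A run is described by one declarative config (YAML mapping); given the same
config and seed the emitted CSV/JSON/PNG outputs are byte-identical.  The
PIV stage — by far the slowest — is cached on disk keyed by a hash of the
config fields that affect it, so threshold-only changes re-use the vectors.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import morphometrics as mm
from . import sequences as seqmod
from .io import ConfigError, FrameStack, load_stack, save_stack, write_metrics
from .kymograph import extract_kymograph, kymograph_to_png
from .outline import outline_to_mask, polygon_area, track_outlines
from .piv import VectorField, piv_stack
from .synthetic import get_preset, render_scenario
from .vorticity import compare_signs, region_vorticity_series, split_cell_halves

__all__ = ["run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name (and frame if known)."""

    def __init__(self, stage: str, message: str, frame: Optional[int] = None):
        self.stage = stage
        self.frame = frame
        at = f" (frame {frame})" if frame is not None else ""
        super().__init__(f"stage '{stage}'{at}: {message}")


def _validate(cfg: dict) -> None:
    inp = cfg.get("input")
    if not isinstance(inp, dict):
        raise ConfigError("config needs an 'input' section")
    if "preset" not in inp:
        for key in ("path", "pixel_size", "frame_interval"):
            if key not in inp:
                raise ConfigError(f"input.{key} is required for file input")
        if inp["pixel_size"] <= 0 or inp["frame_interval"] <= 0:
            raise ConfigError("calibration values must be positive")
    if "dir" not in cfg.get("output", {}):
        raise ConfigError("config needs output.dir")


def _config_hash(cfg: dict, keys) -> str:
    sub = {k: cfg.get(k) for k in keys}
    return hashlib.sha1(
        json.dumps(sub, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _load_input(cfg: dict):
    inp = cfg["input"]
    if "preset" in inp:
        overrides = {k: inp[k] for k in ("n_frames",) if k in inp}
        spec = get_preset(inp["preset"], seed=int(cfg.get("seed", 0)), **overrides)
        stack, truth = render_scenario(spec)
        return stack, truth
    stack = load_stack(inp["path"], inp["pixel_size"], inp["frame_interval"])
    return stack, None


def _piv_cached(cfg: dict, stack: FrameStack, masks, cache_dir: Path):
    piv_cfg = cfg.get("piv", {})
    key = _config_hash(cfg, ["input", "piv", "seed"])
    cache = cache_dir / f"piv_{key}.npz"
    if cache.exists():
        z = np.load(cache, allow_pickle=False)
        fields = []
        for i in range(int(z["n_pairs"])):
            fields.append(VectorField(
                grid_rows=z[f"rows_{i}"], grid_cols=z[f"cols_{i}"],
                dv_row=z[f"dvr_{i}"], dv_col=z[f"dvc_{i}"],
                valid=z[f"ok_{i}"], frame_pair=(i, i + 1),
                pixel_size=stack.pixel_size, frame_interval=stack.frame_interval,
            ))
        return fields
    fields = piv_stack(
        stack, masks=masks,
        initial_window=int(piv_cfg.get("initial_window", 64)),
        final_window=int(piv_cfg.get("final_window", 32)),
        overlap=float(piv_cfg.get("overlap", 0.5)),
        peak_ratio=float(piv_cfg.get("peak_ratio", 1.2)),
    )
    cache_dir.mkdir(parents=True, exist_ok=True)
    payload = {"n_pairs": np.array(len(fields))}
    for i, f in enumerate(fields):
        payload.update({
            f"rows_{i}": f.grid_rows, f"cols_{i}": f.grid_cols,
            f"dvr_{i}": f.dv_row, f"dvc_{i}": f.dv_col, f"ok_{i}": f.valid,
        })
    np.savez(cache, **payload)
    return fields


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_pipeline(cfg: dict, out_dir=None) -> dict:
    """Run every configured stage; returns a dict of output paths.

    Stages are pure functions of the stack and earlier outputs; any failure
    raises :class:`StageError` naming the stage (and frame where known).
    """
    _validate(cfg)
    out = Path(out_dir) if out_dir is not None else Path(cfg["output"]["dir"])
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {}

    try:
        stack, truth = _load_input(cfg)
    except (OSError, ValueError, KeyError) as e:
        raise StageError("input", str(e)) from e

    if cfg["input"].get("save_stack"):
        save_stack(stack, out / "stack.tif")
        paths["stack"] = out / "stack.tif"

    o_cfg = cfg.get("outline", {})
    H, W = stack.shape
    seed_centre = o_cfg.get("seed_centre", (H / 2.0, W / 2.0))
    r_min = float(o_cfg.get("r_min", 10.0))
    r_max = float(o_cfg.get("r_max", min(H, W) / 2.0 - 2.0))
    try:
        outlines = track_outlines(
            stack, seed_centre, r_min, r_max,
            temporal_weight=float(o_cfg.get("temporal_weight", 0.02)),
            smoothing=float(o_cfg.get("smoothing", 0.05)),
        )
    except (RuntimeError, ValueError) as e:
        raise StageError("outline", str(e)) from e

    try:
        profiles = [mm.radial_profile(o, stack.pixel_size) for o in outlines]
        areas = [polygon_area(o, stack.pixel_size) for o in outlines]
    except ValueError as e:
        raise StageError("morphometrics", str(e)) from e
    metrics = mm.profiles_to_table(profiles, areas)
    metrics_path = out / "metrics.csv"
    write_metrics(metrics, metrics_path)
    paths["metrics"] = metrics_path

    seq_cfg = cfg.get("sequences", {})
    diam = np.stack([p.diameters for p in profiles], axis=1)
    sd = np.array([mm.diameter_sd(p) for p in profiles])
    try:
        sequences = seqmod.detect_sequences(
            diam, sd,
            min_extension=float(seq_cfg.get("min_extension", 1.5)),
            smooth_window=int(seq_cfg.get("smooth_window", 3)),
            min_prominence=float(seq_cfg.get("min_prominence", 0.3)),
            frame_interval=stack.frame_interval,
        )
    except ValueError as e:
        raise StageError("sequences", str(e)) from e
    events = {
        "sequences": [
            {
                "angle_deg": s.angle, "start_frame": s.start_frame,
                "peak_frame": s.peak_frame, "end_frame": s.end_frame,
                "out_amplitude_um": round(s.out_amplitude, 6),
                "in_amplitude_um": round(s.in_amplitude, 6),
                "max_inoutin_um": round(s.max_inoutin, 6),
                "duration_min": s.duration,
            }
            for s in sequences
        ]
    }
    el_cfg = cfg.get("elongation")
    if el_cfg:
        ax = seqmod.find_elongation_axis(profiles, int(el_cfg["t0"]), int(el_cfg["t1"]))
        first = None
        if ax.axis_angle is not None:
            idx = int(round(ax.axis_angle / 10.0)) % 18
            first = seqmod.detect_first_step(diam[idx], stack.frame_interval)
        events["elongation"] = {
            "axis_angle_deg": ax.axis_angle, "extension_um": round(ax.extension, 6),
            "first_step_frame": first,
        }
    events_path = out / "events.json"
    _write_json(events, events_path)
    paths["events"] = events_path

    if cfg.get("piv", {}).get("enabled", True):
        masks = [outline_to_mask(o, (H, W)) for o in outlines[:-1]]
        try:
            fields = _piv_cached(cfg, stack, masks, out / "cache")
        except ValueError as e:
            raise StageError("piv", str(e)) from e
        rows = []
        for f in fields:
            rr, cc = np.meshgrid(f.grid_rows, f.grid_cols, indexing="ij")
            for r, c, dvr, dvc, ok in zip(
                rr.ravel(), cc.ravel(), f.dv_row.ravel(), f.dv_col.ravel(),
                f.valid.ravel(),
            ):
                rows.append({
                    "frame": f.frame_pair[0], "row_px": r, "col_px": c,
                    "dv_row_px_frame": dvr, "dv_col_px_frame": dvc,
                    "valid": int(ok),
                })
        vectors_path = out / "vectors.csv"
        write_metrics(pd.DataFrame(rows), vectors_path)
        paths["vectors"] = vectors_path

        try:
            whole = region_vorticity_series(fields, masks, region_id="cell")
            halves = [split_cell_halves(m) for m in masks]
            half_a = region_vorticity_series(
                fields, [h[0] for h in halves], region_id="half-A")
            half_b = region_vorticity_series(
                fields, [h[1] for h in halves], region_id="half-B")
            comparisons = compare_signs(
                half_a, half_b,
                window=float(cfg.get("vorticity", {}).get("window_min", 100.0)),
            )
        except ValueError as e:
            raise StageError("vorticity", str(e)) from e
        vort = pd.DataFrame({
            "time_min": whole.times,
            "mean_vorticity_per_min": whole.mean_vorticity,
            "sign_ccw_positive": whole.sign, "n_valid": whole.n_valid,
            "half_a_vorticity_per_min": half_a.mean_vorticity,
            "half_a_sign": half_a.sign,
            "half_b_vorticity_per_min": half_b.mean_vorticity,
            "half_b_sign": half_b.sign,
        })
        vorticity_path = out / "vorticity.csv"
        write_metrics(vort, vorticity_path)
        paths["vorticity"] = vorticity_path
        sign_rows = [{
            "window_start_min": c.window[0], "window_end_min": c.window[1],
            "a_pos": c.counts[0, 0], "a_neg": c.counts[0, 1],
            "b_pos": c.counts[1, 0], "b_neg": c.counts[1, 1],
            "chi_square": c.chi_square, "p_value": c.p_value,
            "testable": int(c.testable), "yates": int(c.yates),
        } for c in comparisons]
        signs_path = out / "sign_tests.csv"
        write_metrics(pd.DataFrame(sign_rows), signs_path)
        paths["sign_tests"] = signs_path

    kymo_cfg = cfg.get("kymograph")
    if kymo_cfg:
        try:
            kymo = extract_kymograph(
                stack,
                angle=float(kymo_cfg.get("angle", 20.0)),
                length_um=float(kymo_cfg.get("length_um", 50.0)),
                anchor=kymo_cfg.get("anchor", "coa"),
                outlines=outlines,
                segment=kymo_cfg.get("segment", "full"),
                segment_um=kymo_cfg.get("segment_um"),
            )
        except ValueError as e:
            raise StageError("kymograph", str(e)) from e
        kymo_png = out / "kymograph.png"
        kymograph_to_png(kymo, kymo_png)
        pd.DataFrame(
            kymo.image,
            index=[f"{p:.3f}" for p in kymo.positions_um],
        ).to_csv(out / "kymograph.csv", float_format="%.10g")
        paths["kymograph"] = kymo_png

    log = {"config": cfg, "n_frames": len(stack),
           "pixel_size_um": stack.pixel_size,
           "frame_interval_min": stack.frame_interval}
    _write_json(log, out / "run_log.json")
    paths["run_log"] = out / "run_log.json"
    return paths
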