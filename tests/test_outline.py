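import itertools

import numpy as np
import pytest

from zygoflow.io import FrameStack
from zygoflow.outline import (
    Outline,
    SegmentationFailure,
    _dp_closed_path,
    detect_outline,
    outline_radii,
    polygon_area,
    track_outlines,
)

from conftest import circle_outline, disk_image, ellipse_image


def brute_force_closed_path(node, smoothing, max_step):
    """Independent oracle: enumerate every closed path with |dr| <= max_step."""
    A, R = node.shape
    best = -np.inf
    for start in range(R):
        for offs in itertools.product(range(-max_step, max_step + 1), repeat=A - 1):
            r, total, ok = start, node[0, start], True
            for a, o in enumerate(offs, start=1):
                r += o
                if not 0 <= r < R:
                    ok = False
                    break
                total += node[a, r] - smoothing * o * o
            if ok and abs(r - start) <= max_step:
                best = max(best, total - smoothing * (r - start) ** 2)
    return best


class TestDetectOutline:
    def test_disk_radius_recovered(self):
        img = disk_image(80.0)
        o = detect_outline(img, (150, 150), r_min=30, r_max=140)
        r = outline_radii(o)
        assert abs(r.mean() - 80.0) < 1.0
        assert np.allclose(o.centre, (150, 150), atol=1.0)

    def test_ellipse_area_within_2pct(self):
        img = ellipse_image(90.0, 70.0)
        o = detect_outline(img, (256, 256), r_min=30, r_max=250)
        assert abs(polygon_area(o) / (np.pi * 90 * 70) - 1) < 0.02

    def test_infinite_temporal_weight_reproduces_prev(self):
        img = disk_image(80.0)
        prev = detect_outline(img, (150, 150), r_min=30, r_max=140)
        out = detect_outline(img, (150, 150), r_min=30, r_max=140,
                             prev=prev, temporal_weight=1e9)
        assert np.allclose(out.boundary, prev.boundary, atol=1e-9)

    def test_scale_equivariance(self):
        img = disk_image(60.0)
        a = detect_outline(img, (150, 150), r_min=20, r_max=120)
        b = detect_outline(7.5 * img, (150, 150), r_min=20, r_max=120)
        assert np.allclose(a.boundary, b.boundary)

    def test_uniform_image_fails(self):
        with pytest.raises(SegmentationFailure):
            detect_outline(np.full((200, 200), 0.5), (100, 100),
                           r_min=20, r_max=90)

    def test_seed_outside_image(self):
        with pytest.raises(ValueError):
            detect_outline(disk_image(50.0), (400, 10), r_min=10, r_max=60)

    def test_smoothing_reduces_roughness(self, rng):
        img = disk_image(70.0) + rng.normal(0, 0.05, (300, 300))
        rough = []
        for s in (0.0, 0.05, 0.5):
            o = detect_outline(img, (150, 150), r_min=30, r_max=120, smoothing=s)
            r = np.linalg.norm(o.boundary - (150, 150), axis=1)
            rough.append(np.sum(np.diff(np.append(r, r[0])) ** 2))
        assert rough[0] >= rough[1] >= rough[2]


class TestZonaAndPb2Options:
    @staticmethod
    def _ring_image(r_in=90.0, r_out=105.0, shape=(300, 300)):
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             indexing="ij")
        rho = np.hypot(rr - 150, cc - 150)
        img = np.full(shape, 0.6)
        img[(rho >= r_in) & (rho <= r_out)] = 0.25  # dark zona ring
        return img

    def test_edge_polarity_selects_inner_vs_outer_ring_edge(self):
        img = self._ring_image()
        inner = detect_outline(img, (150, 150), r_min=60, r_max=140,
                               edge_polarity="falling")
        outer = detect_outline(img, (150, 150), r_min=60, r_max=140,
                               edge_polarity="rising")
        assert abs(outline_radii(inner).mean() - 90.0) < 2.0
        assert abs(outline_radii(outer).mean() - 105.0) < 2.0

    def test_pb2_band_dilation_encloses_the_bulge(self):
        img = disk_image(70.0)
        rr, cc = np.meshgrid(np.arange(300), np.arange(300), indexing="ij")
        # a 10 px polar-body bulge on the 0-deg ray (above the centre)
        img[np.hypot(rr - (150 - 72), cc - 150) < 10.0] = 0.8
        plain = detect_outline(img, (150, 150), r_min=30, r_max=75)
        withpb = detect_outline(img, (150, 150), r_min=30, r_max=75,
                                pb2_angle=0.0, pb2_extra_px=12.0)
        r_plain = outline_radii(plain, (150, 150))
        r_pb = outline_radii(withpb, (150, 150))
        assert r_pb[0] > r_plain[0] + 4.0       # bulge included at 0 deg
        assert abs(r_pb[180] - r_plain[180]) < 2.0  # far side unchanged


class TestDPOptimality:
    @pytest.mark.parametrize("seed,A,R,max_step", [
        (0, 8, 6, 1), (1, 8, 6, 1), (2, 10, 6, 1), (3, 6, 8, 2),
    ])
    def test_dp_matches_enumeration(self, seed, A, R, max_step):
        r = np.random.default_rng(seed)
        node = r.random((A, R))
        smoothing = 0.1
        total, path = _dp_closed_path(node, smoothing, max_step, range(R))
        expected = brute_force_closed_path(node, smoothing, max_step)
        assert total == pytest.approx(expected, abs=1e-12)
        # the returned path realizes the claimed objective
        obj = node[np.arange(A), path].sum()
        steps = np.diff(np.append(path, path[0]))
        obj -= smoothing * np.sum(steps.astype(float) ** 2)
        assert obj == pytest.approx(total, abs=1e-12)
        assert np.all(np.abs(steps) <= max_step)


class TestTrackOutlines:
    def _stack(self, frames):
        return FrameStack(np.stack(frames), pixel_size=0.5, frame_interval=1.0)

    def test_static_scene_self_consistent(self):
        img = disk_image(70.0)
        stack = self._stack([img] * 5)
        outlines = track_outlines(stack, (150, 150), r_min=30, r_max=120)
        radii = np.stack([outline_radii(o, (150, 150)) for o in outlines])
        assert np.abs(radii - radii[0]).mean() < 1.0

    def test_translation_tracked(self):
        frames = [disk_image(60.0, centre=(140 + 2 * i, 150)) for i in range(6)]
        stack = self._stack(frames)
        outlines = track_outlines(stack, (140, 150), r_min=20, r_max=110)
        centres = np.stack([o.centre for o in outlines])
        steps = np.diff(centres[:, 0])
        assert np.all(np.abs(steps - 2.0) < 0.5)

    def test_noise_frame_interpolated_and_flagged(self, rng):
        img = disk_image(70.0)
        noise = np.full_like(img, 0.5)
        stack = self._stack([img, img, noise, img, img])
        outlines = track_outlines(stack, (150, 150), r_min=30, r_max=120)
        assert outlines[2].interpolated
        assert not outlines[1].interpolated
        r = outline_radii(outlines[2], (150, 150))
        assert abs(r.mean() - 70.0) < 2.0

    def test_mostly_unsegmentable_aborts(self):
        img = disk_image(70.0)
        flat = np.full_like(img, 0.5)
        stack = self._stack([img, flat, flat, flat])
        with pytest.raises(RuntimeError, match="failed"):
            track_outlines(stack, (150, 150), r_min=30, r_max=120)


class TestPolygonArea:
    def test_square_analytic(self):
        o = Outline(np.array(_square_points(100, 40), float))
        assert polygon_area(o, pixel_size=0.5) == pytest.approx(2500.0, rel=1e-9)

    def test_circle_within_1pct(self):
        o = circle_outline(80.0)
        assert polygon_area(o, 0.26) == pytest.approx(
            np.pi * 80**2 * 0.26**2, rel=0.01)

    def test_orientation_invariant(self):
        o = circle_outline(50.0)
        rev = Outline(o.boundary[::-1].copy())
        assert polygon_area(rev) == pytest.approx(polygon_area(o), rel=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            polygon_area(circle_outline(1.5))  # area < 10 px^2


def _square_points(side, per_edge):
    """Vertices of an axis-aligned square traversed with per-edge sampling."""
    t = np.linspace(0, side, per_edge, endpoint=False)
    top = [(0.0, float(x)) for x in t]
    right = [(float(y), float(side)) for y in t]
    bottom = [(float(side), float(side - x)) for x in t]
    left = [(float(side - y), 0.0) for y in t]
    return top + right + bottom + left
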