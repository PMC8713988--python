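import numpy as np
import pytest

from zygoflow.piv import VectorField
from zygoflow.vorticity import (
    VorticitySeries,
    _chi2_on_table,
    compare_signs,
    region_vorticity_series,
    split_cell_halves,
    vorticity_field,
)

PX, FI = 0.5, 2.0


def rotation_field(omega_rad_min, centre=(128.0, 128.0), n=14, step=16.0,
                   valid=None):
    """Solid-body rotation sampled on a PIV grid (px/frame vectors)."""
    g = np.arange(1, n + 1) * step
    rr, cc = np.meshgrid(g, g, indexing="ij")
    phi = omega_rad_min * FI
    dvr = -phi * (cc - centre[1])
    dvc = phi * (rr - centre[0])
    return VectorField(
        g, g, dvr, dvc,
        np.ones((n, n), bool) if valid is None else valid,
        pixel_size=PX, frame_interval=FI,
    )


def sign_series(signs, region_id="r", fi=FI):
    s = np.asarray(signs, int)
    return VorticitySeries(
        region_id=region_id,
        times=np.arange(s.size, dtype=float) * fi,
        mean_vorticity=s * 0.02,
        sign=s,
        n_valid=np.full(s.size, 10),
    )


class TestVorticityField:
    def test_solid_body_gives_twice_omega(self):
        omega = 0.05
        v = vorticity_field(rotation_field(omega))
        assert np.isfinite(v).all()
        assert abs(np.nanmean(v) / (2 * omega) - 1) < 0.10

    def test_uniform_translation_is_curl_free(self):
        f = rotation_field(0.0)
        f.dv_row += 1.0
        f.dv_col += -2.0
        v = vorticity_field(f)
        assert np.nanmax(np.abs(v)) < 0.005

    def test_robust_to_40pct_invalid(self):
        omega = 0.05
        rng = np.random.default_rng(5)
        valid = rng.random((14, 14)) > 0.4
        v = vorticity_field(rotation_field(omega, valid=valid))
        assert abs(np.nanmean(v) / (2 * omega) - 1) < 0.15

    def test_sign_antisymmetry(self):
        f = rotation_field(0.03)
        g = rotation_field(-0.03)
        vf, vg = vorticity_field(f), vorticity_field(g)
        assert np.allclose(np.nan_to_num(vf), -np.nan_to_num(vg), atol=1e-12)

    def test_90deg_rotation_invariance(self):
        f = rotation_field(0.04)
        # rotating grid and vectors by 90 deg CCW-displayed:
        # (row, col) -> (row', col') with row' = -col, col' = row (about centre)
        g = rotation_field(0.04)
        g.dv_row, g.dv_col = -f.dv_col.T[::-1].copy(), f.dv_row.T[::-1].copy()
        va, vb = np.nanmean(vorticity_field(f)), np.nanmean(vorticity_field(g))
        assert abs(vb / va - 1) < 0.05

    def test_matches_central_difference_curl_on_linear_fields(self, rng):
        # u, v linear in x, y -> both estimators are exact
        g = np.arange(1, 13) * 16.0
        rr, cc = np.meshgrid(g, g, indexing="ij")
        a, b, c, d = 0.01, -0.02, 0.015, 0.03
        dvc = a * cc + b * rr   # u (col direction)
        dvr = c * cc + d * rr   # row direction
        f = VectorField(g, g, dvr, dvc, np.ones((12, 12), bool),
                        pixel_size=PX, frame_interval=FI)
        v = vorticity_field(f)
        # analytic curl in y-up um/min coordinates
        x = cc * PX
        y = -rr * PX
        u = dvc * PX / FI
        w = -dvr * PX / FI
        du_dy = np.gradient(u, -g * PX, axis=0)
        dw_dx = np.gradient(w, g * PX, axis=1)
        expected = dw_dx - du_dy
        assert np.abs(v - expected).max() < 1e-6

    def test_too_few_vectors_gives_empty_field(self):
        f = rotation_field(0.05, valid=np.zeros((14, 14), bool))
        assert np.isnan(vorticity_field(f)).all()


class TestRegionSeries:
    def test_constant_vortex_has_constant_sign(self):
        fields = [rotation_field(0.03) for _ in range(6)]
        for i, f in enumerate(fields):
            f.frame_pair = (i, i + 1)
        mask = np.ones((256, 256), bool)
        s = region_vorticity_series(fields, mask, "cell")
        assert (s.sign == 1).all()
        assert np.allclose(s.times, np.arange(6) * FI)

    def test_mirrored_vortices_have_opposite_signs(self):
        f_cw = rotation_field(-0.03, centre=(120.0, 60.0))
        f_ccw = rotation_field(0.03, centre=(120.0, 180.0))
        mask = np.ones((256, 256), bool)
        a = region_vorticity_series([f_cw], mask, "cell-1")
        b = region_vorticity_series([f_ccw], mask, "cell-2")
        assert a.sign[0] == -1 and b.sign[0] == 1

    def test_noise_floor_gives_sign_zero(self, rng):
        g = np.arange(1, 15) * 16.0
        noise = rng.normal(0, 0.002, (14, 14))
        f = VectorField(g, g, noise, -noise.T, np.ones((14, 14), bool),
                        pixel_size=PX, frame_interval=FI)
        s = region_vorticity_series([f], np.ones((256, 256), bool), "q")
        assert s.sign[0] == 0

    def test_empty_region_rejected(self):
        f = rotation_field(0.03)
        with pytest.raises(ValueError, match="empty"):
            region_vorticity_series([f], np.zeros((256, 256), bool), "x")


class TestSplitHalves:
    @staticmethod
    def _ellipse_mask(a=60, b=40, centre=(100, 100), shape=(200, 200), rot=30.0):
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             indexing="ij")
        t = np.deg2rad(rot)
        x = (cc - centre[1]) * np.cos(t) + (rr - centre[0]) * np.sin(t)
        y = -(cc - centre[1]) * np.sin(t) + (rr - centre[0]) * np.cos(t)
        return (x / a) ** 2 + (y / b) ** 2 <= 1.0

    def test_ellipse_halves_equal_area(self):
        mask = self._ellipse_mask()
        a, b = split_cell_halves(mask)
        assert abs(a.sum() - b.sum()) / mask.sum() < 0.02
        assert not (a & b).any()
        assert ((a | b) == mask).all()

    def test_annotated_axis_takes_precedence(self):
        mask = self._ellipse_mask(rot=0.0)
        # an explicit vertical axis splits top/bottom instead of left/right
        a, b = split_cell_halves(mask, axis=((40.0, 100.0), (160.0, 100.0)))
        rows_a = np.nonzero(a)[0]
        rows_b = np.nonzero(b)[0]
        assert rows_a.max() < rows_b.min()

    def test_l_shape_halves_tile_the_mask(self):
        mask = np.zeros((100, 100), bool)
        mask[10:90, 10:30] = True
        mask[70:90, 10:90] = True
        a, b = split_cell_halves(mask)
        assert not (a & b).any()
        assert ((a | b) == mask).all()

    def test_degenerate_mask_rejected(self):
        with pytest.raises(ValueError):
            split_cell_halves(np.zeros((50, 50), bool))


class TestCompareSigns:
    def test_perfect_separation_matches_closed_form(self):
        a = sign_series([1] * 20)
        b = sign_series([-1] * 20)
        (c,) = compare_signs(a, b)
        # 2x2 Pearson chi-squared closed form: N (ad-bc)^2 / row/col products
        assert c.chi_square == pytest.approx(40.0, rel=1e-12)
        assert c.p_value < 0.001
        assert not c.yates  # all expected counts are 10

    def test_small_counts_use_yates(self):
        a = sign_series([1] * 4 + [0] * 2, fi=1.0)
        b = sign_series([-1] * 4 + [0] * 2, fi=1.0)
        (c,) = compare_signs(a, b, min_count=4)
        # Yates on [[4,0],[0,4]]: (|16| - 4)^2 * 8 / 256
        assert c.yates
        assert c.chi_square == pytest.approx(4.5, rel=1e-12)

    def test_identical_series_give_zero_chi_square(self):
        a = sign_series([1] * 12 + [-1] * 8)
        b = sign_series([1] * 12 + [-1] * 8)
        (c,) = compare_signs(a, b)
        assert c.chi_square == 0.0
        assert c.p_value == 1.0

    def test_all_zero_region_untestable(self):
        a = sign_series([0] * 20)
        b = sign_series([1] * 20)
        (c,) = compare_signs(a, b)
        assert not c.testable
        assert np.isnan(c.chi_square)

    def test_windows_partition_the_series(self):
        a = sign_series([1] * 120)
        b = sign_series([-1] * 120)
        comps = compare_signs(a, b, window=100.0)
        assert [c.window for c in comps] == [(0.0, 100.0), (100.0, 200.0),
                                             (200.0, 300.0)]
        assert all(c.p_value < 0.01 for c in comps)

    def test_zero_sign_frames_excluded_from_counts(self):
        a = sign_series([1, 1, 0, 1, 1, 0, 1, 1, 0, 1])
        b = sign_series([-1] * 10)
        (c,) = compare_signs(a, b)
        assert c.counts[0].sum() == 7
        assert c.counts[1].sum() == 10

    def test_fisher_option_agrees_on_perfect_separation(self):
        a = sign_series([1] * 10)
        b = sign_series([-1] * 10)
        (c,) = compare_signs(a, b, method="fisher")
        assert c.p_value < 0.001
        assert np.isnan(c.chi_square)

    def test_disjoint_series_rejected(self):
        a = sign_series([1] * 5)
        b = sign_series([1] * 5)
        b.times = b.times + 1000.0
        with pytest.raises(ValueError):
            compare_signs(a, b)


def test_chi2_degenerate_table_is_zero():
    chi2, p, yates = _chi2_on_table(np.array([[20, 0], [20, 0]]))
    assert chi2 == 0.0 and p == 1.0
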