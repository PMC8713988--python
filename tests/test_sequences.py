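import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zygoflow.morphometrics import RadialProfile
from zygoflow.sequences import (
    detect_first_step,
    detect_indents,
    detect_sequences,
    find_elongation_axis,
)

from conftest import ellipse_outline, polygon_outline

ANGLES = np.arange(0.0, 180.0, 10.0)


def make_series(T=60, base=70.0, cycles=()):
    """18 x T diameter series (um) with half-sine cycles injected.

    ``cycles`` items: (angle_deg, amplitude_um, t0, t1).
    """
    d = np.full((18, T), base)
    t = np.arange(T)
    for angle, amp, t0, t1 in cycles:
        idx = int(angle // 10)
        window = (t >= t0) & (t <= t1)
        d[idx, window] += amp * np.sin(
            np.pi * (t[window] - t0) / (t1 - t0))
    sd = np.std(d, axis=0, ddof=1)
    return d, sd


class TestDetectSequences:
    def test_single_cycle_recovered(self):
        d, sd = make_series(cycles=[(140.0, 3.0, 10, 30)])
        seqs = detect_sequences(d, sd, frame_interval=2.0)
        assert len(seqs) == 1
        s = seqs[0]
        assert s.angle == 140.0
        assert s.max_inoutin == pytest.approx(3.0, abs=0.1)
        assert s.start_frame <= 10 and s.end_frame >= 30
        assert s.duration == (s.end_frame - s.start_frame) * 2.0

    def test_subthreshold_cycle_ignored(self):
        d, sd = make_series(cycles=[(140.0, 1.0, 10, 30)])
        assert detect_sequences(d, sd) == []

    def test_constant_series_yields_nothing(self):
        d, sd = make_series()
        assert detect_sequences(d, sd) == []

    def test_multiple_disjoint_cycles_all_found(self):
        cycles = [(30.0, 2.5, 5, 20), (120.0, 4.0, 25, 40), (70.0, 2.0, 45, 58)]
        d, sd = make_series(T=64, cycles=cycles)
        seqs = detect_sequences(d, sd)
        assert [s.angle for s in seqs] == [30.0, 120.0, 70.0]
        for s, (_, amp, _, _) in zip(seqs, cycles):
            assert s.max_inoutin == pytest.approx(amp, abs=0.25)

    def test_every_reported_sequence_obeys_the_rule(self, rng):
        d, sd = make_series(T=80, cycles=[(50.0, 3.0, 10, 30), (90.0, 2.0, 40, 60)])
        d += rng.normal(0, 0.05, d.shape)
        sd = np.std(d, axis=0, ddof=1)
        for s in detect_sequences(d, sd):
            assert s.out_amplitude >= 1.5
            assert s.in_amplitude > 0

    @given(offset=st.floats(-50.0, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_translation_invariance(self, offset):
        d, sd = make_series(cycles=[(140.0, 3.0, 10, 30)])
        a = detect_sequences(d, sd)
        b = detect_sequences(d + offset, sd)
        assert [(s.angle, s.start_frame, s.peak_frame, s.end_frame) for s in a] \
            == [(s.angle, s.start_frame, s.peak_frame, s.end_frame) for s in b]

    def test_too_short_series_rejected(self):
        d, sd = make_series(T=2)
        with pytest.raises(ValueError):
            detect_sequences(d, sd)


def _profiles_from_diameters(diams_by_frame):
    out = []
    for t, d in diams_by_frame.items():
        radii = np.concatenate([np.asarray(d) / 2.0] * 2)
        out.append(RadialProfile(t, radii, np.array([0.0, 0.0]), 0.5))
    return out


class TestElongationAxis:
    def test_grown_diameter_found(self):
        d0 = np.full(18, 70.0)
        d1 = d0.copy()
        d1[3] += 12.0  # 30 degrees
        ev = find_elongation_axis(_profiles_from_diameters({0: d0, 5: d1}), 0, 5)
        assert ev.axis_angle == 30.0
        assert ev.extension == pytest.approx(12.0)
        assert not ev.tie

    def test_no_change_is_indeterminate(self):
        d = np.full(18, 70.0)
        ev = find_elongation_axis(_profiles_from_diameters({0: d, 5: d}), 0, 5)
        assert ev.axis_angle is None
        assert ev.extension == 0.0

    def test_tie_flagged_and_smaller_angle_wins(self):
        d0 = np.full(18, 70.0)
        d1 = d0.copy()
        d1[[2, 7]] += 5.0
        ev = find_elongation_axis(_profiles_from_diameters({0: d0, 1: d1}), 0, 1)
        assert ev.axis_angle == 20.0
        assert ev.tie

    def test_missing_profile_rejected(self):
        d = np.full(18, 70.0)
        with pytest.raises(ValueError, match="missing"):
            find_elongation_axis(_profiles_from_diameters({0: d}), 0, 5)


class TestFirstStep:
    def test_ramp_crossing_detected_at_construction_frame(self):
        # 2-min frames; flat until frame 20, then 0.6 um/min -> 1.2 um per
        # 2-min interval, first crossing the 1 um rule at frame 20
        t = np.arange(60)
        d = 70.0 + np.where(t >= 20, (t - 20) * 1.2, 0.0)
        assert detect_first_step(d, frame_interval=2.0) == 20

    def test_shallow_ramp_never_fires(self):
        t = np.arange(60)
        d = 70.0 + t * 0.4  # 0.4 um per 2-min frame < 1 um rule
        assert detect_first_step(d, frame_interval=2.0) is None

    def test_flat_series_none(self):
        assert detect_first_step(np.full(30, 70.0), frame_interval=2.0) is None

    def test_zero_threshold_fires_at_first_positive_increment(self):
        d = np.array([70.0] * 10 + [70.2, 70.4, 70.6] + [70.6] * 5)
        assert detect_first_step(d, 2.0, threshold=0.0) == 9

    def test_fractional_window_rounded_with_warning(self):
        d = np.linspace(70, 90, 30)
        with pytest.warns(UserWarning, match="frames"):
            detect_first_step(d, frame_interval=1.5, window=2.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_first_step(np.array([70.0]), 2.0)


class TestDetectIndents:
    def test_convex_ellipse_has_none(self):
        o = ellipse_outline(90.0, 60.0)
        assert detect_indents(o, min_depth=1.0, pixel_size=0.5) == []

    def test_dumbbell_has_two_opposed_indents(self):
        def rfn(theta):
            t = np.asarray(theta, float)
            dip = 16.0 * (np.exp(-0.5 * ((t - 90) / 10.0) ** 2)
                          + np.exp(-0.5 * ((t - 270) / 10.0) ** 2))
            return 100.0 - dip
        o = polygon_outline(rfn)
        hits = detect_indents(o, min_depth=4.0, pixel_size=0.5)
        assert len(hits) == 2
        angles = sorted(a for a, _ in hits)
        assert abs(angles[0] - 90.0) < 10.0
        assert abs((angles[1] - angles[0]) - 180.0) < 10.0
        # depth is measured against the local convex hull, which chords the
        # dip, so it is positive but smaller than the full 8 um excursion
        for _, depth in hits:
            assert 4.0 <= depth <= 8.0

    def test_min_depth_above_concavity_yields_none(self):
        def rfn(theta):
            t = np.asarray(theta, float)
            return 100.0 - 6.0 * np.exp(-0.5 * ((t - 90) / 10.0) ** 2)
        o = polygon_outline(rfn)
        assert detect_indents(o, min_depth=10.0, pixel_size=0.5) == []
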