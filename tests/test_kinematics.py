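"""Movement-quality pipeline: Savitzky-Golay filtering, 5%-of-peak
segmentation, MAPR, spectral arc length, and normalized speed."""

import numpy as np
import pytest
from scipy.signal import freqz, savgol_coeffs

from rehabsim.kinematics import (
    MovementSegment,
    SegmentationError,
    mapr,
    movement_metrics,
    normalized_speed,
    segment_movement,
    sg_window,
    smooth_series,
    spectral_arc_length,
)
from rehabsim.subject import synth_speed_profile


def sal_dense_oracle(speed, rate, omega_c=10.0, n_freq=4001):
    """Independent fine-grid DTFT + arc-length integration."""
    t = np.arange(speed.size) / rate
    f = np.linspace(0, omega_c, n_freq)
    V = np.abs(np.exp(-2j * np.pi * np.outer(f, t)) @ speed)
    Vh = V / V[0]
    u = f / omega_c
    dV = np.gradient(Vh, u)
    return -np.trapezoid(np.sqrt(1.0 + dV**2), u)


def crop_at_threshold(speed, rate, frac=0.05):
    thr = frac * speed.max()
    idx = np.flatnonzero(speed >= thr)
    return MovementSegment(idx[0] / rate, idx[-1] / rate, speed[idx[0] : idx[-1] + 1], rate)


class TestSmoothing:
    def test_window_selection(self):
        assert sg_window(100) == 21
        assert sg_window(200) == 41

    def test_constant_series_unchanged(self):
        x = np.full(100, 3.7)
        assert np.allclose(smooth_series(x, 100), x)

    def test_cubic_reproduced_in_interior(self):
        t = np.linspace(0, 1, 200)
        x = 2 - t + 3 * t**2 - 0.5 * t**3
        y = smooth_series(x, 200)
        assert np.allclose(y[25:-25], x[25:-25], atol=1e-10)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            smooth_series(np.zeros(10), 100)

    def test_rate_matched_windows_equivalent_below_10hz(self):
        grids = []
        for rate in (100.0, 200.0):
            c = savgol_coeffs(sg_window(rate), 3)
            f, h = freqz(c, worN=4096, fs=rate)
            grids.append((f, np.abs(h)))
        f_common = np.linspace(0, 10, 400)
        h1 = np.interp(f_common, *grids[0])
        h2 = np.interp(f_common, *grids[1])
        assert np.max(np.abs(h1 - h2)) < 0.05


class TestSegmentation:
    def test_recovers_known_crossings_of_single_pulse(self):
        prof = synth_speed_profile([(12.0, 0.3, 1.2)], rate=100)
        t_in, t_fin = prof.true_crossings(0.05)
        seg = segment_movement(prof.time, prof.speed, t0=0.0, t_tar=prof.time[-1],
                               direction=+1, rate=100)
        assert abs(seg.t_in - t_in) <= 2 / 100
        assert abs(seg.t_fin - t_fin) <= 2 / 100

    def test_post_reach_corrective_pulse_toward_target_extends(self):
        # overshoot correction after the registered reach is part of movement
        rate = 100.0
        prof = synth_speed_profile([(12.0, 0.2, 1.0), (3.0, 1.7, 0.5)], rate)
        v = prof.speed.copy()  # both pulses toward target
        t_tar = 1.3  # software registers the reach before the correction
        seg = segment_movement(prof.time, v, t0=0.0, t_tar=t_tar, direction=+1, rate=rate)
        assert seg.t_fin > 1.7

    def test_post_reach_pulse_away_from_target_ignored(self):
        rate = 100.0
        prof1 = synth_speed_profile([(12.0, 0.2, 1.0)], rate, duration=2.4)
        prof2 = synth_speed_profile([(3.0, 1.7, 0.5)], rate, duration=2.4)
        v = prof1.speed - prof2.speed  # second pulse reverses direction
        seg = segment_movement(prof1.time, v, t0=0.0, t_tar=1.3, direction=+1, rate=rate)
        t_fin_single = prof1.true_crossings(0.05)[1]
        assert seg.t_fin == pytest.approx(t_fin_single, abs=3 / rate)

    def test_no_movement_in_window_raises(self):
        t = np.arange(0, 2, 0.01)
        v = np.zeros_like(t)
        v[150:] = 5.0  # movement only after t_tar
        with pytest.raises(SegmentationError):
            segment_movement(t, v, t0=0.0, t_tar=1.0, direction=+1, rate=100)

    def test_nearby_regions_merged_before_classification(self):
        rate = 100.0
        prof = synth_speed_profile([(12.0, 0.2, 1.0), (6.0, 1.3, 0.4)], rate)
        # 100 ms gap < 150 ms merge window -> single movement to the far crossing
        seg = segment_movement(prof.time, prof.speed, t0=0.0, t_tar=prof.time[-1],
                               direction=+1, rate=rate)
        assert seg.t_fin > 1.5


class TestMetrics:
    def test_mapr_constant_speed_is_100(self):
        seg = MovementSegment(0, 1, np.full(100, 5.0), 100)
        assert mapr(seg) == 100.0

    def test_mapr_half_suprathreshold_is_50(self):
        speed = np.concatenate([np.full(50, 10.0), np.full(50, 0.1)])
        seg = MovementSegment(0, 1, speed, 100)
        assert mapr(seg) == pytest.approx(50.0)

    def test_mapr_matches_brute_force_counting(self):
        prof = synth_speed_profile([(10.0, 0.0, 1.0), (2.0, 0.8, 0.6)], rate=100)
        seg = crop_at_threshold(prof.speed, 100)
        thr = 0.05 * seg.speed.max()
        count = sum(1 for s in seg.speed if s >= thr)  # independent loop oracle
        assert mapr(seg) == pytest.approx(100.0 * count / seg.speed.size)

    def test_norm_speed_constant_profile(self):
        seg = MovementSegment(0, 1, np.full(50, 2.0), 100)
        assert normalized_speed(seg) == 1.0

    def test_norm_speed_triangular_profile(self):
        tri = np.concatenate([np.linspace(0, 10, 101), np.linspace(10, 0, 101)[1:]])
        seg = MovementSegment(0, 2, tri, 100)
        assert normalized_speed(seg) == pytest.approx(0.5, abs=0.01)

    def test_norm_speed_full_min_jerk_is_8_15(self):
        prof = synth_speed_profile([(10.0, 0.0, 1.0)], rate=1000, duration=1.0)
        seg = MovementSegment(0, 1, prof.speed, 1000)
        assert normalized_speed(seg) == pytest.approx(8.0 / 15.0, abs=1e-4)

    def test_sal_matches_dense_grid_oracle(self):
        prof = synth_speed_profile([(10.0, 0.0, 1.0)], rate=100, duration=1.0)
        seg = MovementSegment(0, 1, prof.speed, 100)
        assert spectral_arc_length(seg) == pytest.approx(
            sal_dense_oracle(prof.speed, 100), abs=1e-3
        )

    def test_sal_amplitude_invariant(self):
        prof = synth_speed_profile([(10.0, 0.0, 1.0)], rate=100, duration=1.0)
        a = spectral_arc_length(MovementSegment(0, 1, prof.speed, 100))
        b = spectral_arc_length(MovementSegment(0, 1, 2 * prof.speed, 100))
        assert a == b

    def test_sal_overlapping_corrective_pulse_more_negative(self):
        rate = 100.0
        single = synth_speed_profile([(10.0, 0.0, 1.0)], rate)
        double = synth_speed_profile([(10.0, 0.0, 1.0), (4.0, 0.8, 0.6)], rate)
        s1 = spectral_arc_length(crop_at_threshold(single.speed, rate))
        s2 = spectral_arc_length(crop_at_threshold(double.speed, rate))
        assert s2 < s1

    def test_sal_bounded_above_by_minus_one(self):
        prof = synth_speed_profile([(10.0, 0.0, 1.0)], rate=100)
        assert spectral_arc_length(crop_at_threshold(prof.speed, 100)) <= -1.0

    def test_all_zero_speed_undefined(self):
        seg = MovementSegment(0, 1, np.zeros(50) + 1e-30, 100)
        with pytest.raises(ValueError):
            normalized_speed(MovementSegment(0, 1, np.zeros(50), 100))
        with pytest.raises(ValueError):
            spectral_arc_length(MovementSegment(0, 1, np.zeros(50), 100))
        del seg


class TestMetricInvariants:
    def test_amplitude_scaling_invariance(self):
        prof = synth_speed_profile([(10.0, 0.1, 1.0), (2.0, 0.9, 0.5)], rate=100)
        seg1 = crop_at_threshold(prof.speed, 100)
        seg2 = crop_at_threshold(3.5 * prof.speed, 100)
        m1, m2 = movement_metrics(seg1), movement_metrics(seg2)
        assert m1.mapr == pytest.approx(m2.mapr)
        assert m1.sal == pytest.approx(m2.sal)
        assert m1.norm_speed == pytest.approx(m2.norm_speed)

    def test_added_submovement_never_improves_metrics(self):
        # randomized corrective-submovement family; SAL is allowed rare
        # exceptions because longer movements compress the spectrum
        rng = np.random.default_rng(0)
        rate = 100.0
        bad_mapr = bad_sal = bad_ns = 0
        n = 200
        for _ in range(n):
            A = rng.uniform(10, 20)
            d = rng.uniform(0.8, 1.2)
            a2 = rng.uniform(0.1, 0.4) * A
            gap = rng.uniform(0.2, 0.5)
            d2 = rng.uniform(0.3, 0.6)
            dur = 0.1 + d + gap + d2 + 0.2
            p1 = synth_speed_profile([(A, 0.1, d)], rate, duration=dur)
            p2 = synth_speed_profile([(A, 0.1, d), (a2, 0.1 + d + gap, d2)], rate, duration=dur)
            s1, s2 = crop_at_threshold(p1.speed, rate), crop_at_threshold(p2.speed, rate)
            bad_mapr += mapr(s2) > mapr(s1) + 1e-9
            bad_sal += spectral_arc_length(s2) > spectral_arc_length(s1) + 1e-9
            bad_ns += normalized_speed(s2) > normalized_speed(s1) + 1e-9
        assert bad_mapr == 0
        assert bad_ns == 0
        assert bad_sal <= 0.01 * n
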