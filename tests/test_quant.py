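import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cordmotion.movie import MovieTensor
from cordmotion.quant import (
    EncoderTrace,
    bead_profile_normalize,
    bodypart_speed,
    chaplan_updown,
    cross_camera_intensity_normalize,
    decode_pulses,
    encoder_conversion_factor,
    encoder_speed,
    load_k_table,
    microglia_ratio,
    stimulus_response_map,
    sudo_threshold,
)


class TestEncoder:
    def test_conversion_factor_printed_value(self):
        # Cp = 2*pi*6.6/600 cm per pulse
        assert encoder_conversion_factor(6.6, 600) == pytest.approx(0.0691144, rel=1e-4)

    def test_no_pulses_zero_speed(self):
        trace = EncoderTrace(np.zeros(50, int), np.zeros(50, int), 100.0)
        np.testing.assert_array_equal(encoder_speed(trace), 0.0)

    def test_full_revolution_speed(self):
        # 600 CW pulses in one second = one wheel revolution = 2*pi*6.6 cm/s
        a = np.zeros(1200, int)
        a[::2] = 1
        trace = EncoderTrace(a, np.zeros(1200, int), 1200.0)
        mean_speed = encoder_speed(trace).mean()
        assert mean_speed == pytest.approx(2 * np.pi * 6.6, rel=0.01)

    def test_channel_swap_flips_direction(self):
        rng = np.random.default_rng(0)
        a = (rng.random(100) < 0.2).astype(int)
        b = np.zeros(100, int)
        cw, ccw = decode_pulses(EncoderTrace(a, b, 100.0))
        cw2, ccw2 = decode_pulses(EncoderTrace(b, a, 100.0))
        np.testing.assert_array_equal(cw[:-1], -ccw2[:-1])
        np.testing.assert_array_equal(ccw[:-1], -cw2[:-1])

    def test_pulse_counts_exact(self):
        # isolated single-sample pulses decode one-for-one
        a = np.zeros(30, int)
        b = np.zeros(30, int)
        a[[3, 7, 15]] = 1
        b[[20, 25]] = 1
        cw, ccw = decode_pulses(EncoderTrace(a, b, 100.0))
        assert cw.sum() == 3
        assert ccw.sum() == -2

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            EncoderTrace(np.array([0, 2]), np.array([0, 0]), 10.0)


class TestBodypartSpeed:
    def make_track(self, xs, ys, lk=1.0):
        n = len(xs)
        return pd.DataFrame(
            {"x": xs, "y": ys, "likelihood": np.full(n, lk) if np.isscalar(lk) else lk}
        )

    def test_stationary_point_zero(self):
        track = self.make_track([5.0] * 10, [7.0] * 10)
        np.testing.assert_allclose(bodypart_speed(track, 20, 5), 0.0)

    def test_formula_arithmetic(self):
        # 10 px/frame at 20 fps and 5 px/cm -> 40 cm/s
        xs = np.arange(10) * 10.0
        track = self.make_track(xs, np.zeros(10))
        speed = bodypart_speed(track, 20, 5)
        assert speed[0] == 0.0
        np.testing.assert_allclose(speed[1:], 40.0)

    def test_low_likelihood_frames_excluded(self):
        lk = np.ones(10)
        lk[4] = 0.05
        track = self.make_track(np.arange(10) * 2.0, np.zeros(10), lk)
        speed = bodypart_speed(track, 20, 5, min_likelihood=0.1)
        assert np.isnan(speed[4]) and np.isnan(speed[5])
        assert np.isfinite(speed[2])

    def test_smoothing_spreads_spike_preserving_area(self):
        xs = np.zeros(300)
        xs[150:] = 50.0  # single 50-px jump
        track = self.make_track(xs, np.zeros(300))
        raw = bodypart_speed(track, 20, 5)
        smooth = bodypart_speed(track, 20, 5, smooth_window_s=5.0)
        assert smooth.max() < raw.max()
        assert np.nansum(smooth) == pytest.approx(np.nansum(raw), rel=1e-6)
        assert (smooth > 0).sum() >= 100

    def test_too_few_valid_frames(self):
        track = self.make_track([1.0, 2.0], [0.0, 0.0], lk=0.0)
        with pytest.raises(ValueError):
            bodypart_speed(track, 20, 5)


class TestVonFrey:
    def test_sudo_printed_formula(self):
        # F = 5, responded: 10^(0.24*4.5 - 1.54) = 10^-0.46
        assert sudo_threshold(5, True) == pytest.approx(10**-0.46, rel=1e-12)

    def test_sudo_monotone_in_filament(self):
        for responded in (True, False):
            vals = [sudo_threshold(f, responded) for f in range(1, 10)]
            assert np.all(np.diff(vals) > 0)

    def test_sudo_response_factor(self):
        # same filament, responded vs not: exactly a factor 10^0.24
        ratio = sudo_threshold(5, False) / sudo_threshold(5, True)
        assert ratio == pytest.approx(10**0.24, rel=1e-12)

    def test_sudo_range_check(self):
        with pytest.raises(ValueError):
            sudo_threshold(0, True)

    def test_chaplan_k_zero_returns_force(self):
        assert chaplan_updown(0.6, 0.0, 0.3) == pytest.approx(0.6)

    def test_chaplan_formula_arithmetic(self):
        assert chaplan_updown(1.0, 1.0, 0.3) == pytest.approx(10**0.3)

    def test_chaplan_monotone_in_k(self):
        vals = [chaplan_updown(0.6, k, 0.3) for k in (-1.0, 0.0, 1.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_chaplan_invalid_force(self):
        with pytest.raises(ValueError):
            chaplan_updown(0.0, 1.0, 0.3)

    def test_k_table_loader(self, tmp_path):
        path = tmp_path / "k.csv"
        path.write_text("pattern,k\nXOX,0.5\nOXX,-0.25\n")
        table = load_k_table(path)
        assert table == {"XOX": 0.5, "OXX": -0.25}
        bad = tmp_path / "bad.csv"
        bad.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError):
            load_k_table(bad)


class TestMicrogliaRatio:
    def test_equal_sides_zero(self):
        r, _ = microglia_ratio(np.ones(5), np.ones(5))
        np.testing.assert_array_equal(r, 0.0)

    def test_printed_example(self):
        r, _ = microglia_ratio(np.array([3.0]), np.array([1.0]))
        assert r[0] == pytest.approx(0.5)

    @given(
        st.lists(st.floats(0.01, 1e6), min_size=1, max_size=20),
        st.lists(st.floats(0.01, 1e6), min_size=1, max_size=20),
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry_and_bounds(self, fi, fc):
        n = min(len(fi), len(fc))
        fi = np.array(fi[:n])
        fc = np.array(fc[:n])
        r, _ = microglia_ratio(fi, fc)
        r_swapped, _ = microglia_ratio(fc, fi)
        np.testing.assert_allclose(r, -r_swapped, atol=1e-12)
        assert np.all(r >= -1.0) and np.all(r <= 1.0)

    def test_baseline_normalization(self):
        r, norm = microglia_ratio(
            np.array([2.0, 2.0, 3.0, 3.0]), np.array([1.0, 1.0, 1.0, 1.0]),
            baseline_sessions=slice(0, 2),
        )
        np.testing.assert_allclose(norm[:2], 0.0, atol=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            microglia_ratio(np.array([0.0]), np.array([0.0]))


class TestStimulusResponseMap:
    def test_zero_movie_zero_map_no_contours(self):
        movie = MovieTensor(np.zeros((20, 16, 16)), frame_rate=10.0)
        proj, contours = stimulus_response_map(movie, [2, 10], contour_thresholds=[0.1])
        np.testing.assert_array_equal(proj, 0.0)
        assert contours == {}

    def test_gaussian_activation_peak_location(self, rng):
        yy, xx = np.mgrid[0:32, 0:32]
        blob = np.exp(-(((yy - 20) ** 2 + (xx - 11) ** 2) / (2 * 3.0**2)))
        data = rng.normal(0, 0.01, size=(30, 32, 32))
        for s in (5, 15):
            data[s : s + 6] += blob
        movie = MovieTensor(data, frame_rate=2.0)
        proj, _ = stimulus_response_map(movie, [5, 15])
        py, px = np.unravel_index(np.argmax(proj), proj.shape)
        assert abs(py - 20) <= 2 and abs(px - 11) <= 2

    def test_two_zones_two_outermost_contours(self):
        yy, xx = np.mgrid[0:48, 0:48]
        z1 = np.exp(-(((yy - 12) ** 2 + (xx - 12) ** 2) / 18.0))
        z2 = np.exp(-(((yy - 36) ** 2 + (xx - 36) ** 2) / 18.0))
        movie = MovieTensor(np.stack([z1 + z2] * 6), frame_rate=2.0)
        proj, contours = stimulus_response_map(
            movie, [0], window=6, contour_thresholds=[0.3]
        )
        from skimage import measure

        all_contours = measure.find_contours(proj, 0.3)
        assert len(all_contours) == 2  # one outermost edge per zone
        assert 0.3 in contours

    def test_linearity_in_dff(self, rng):
        data = rng.random((12, 8, 8))
        m1 = MovieTensor(data, frame_rate=4.0)
        m2 = MovieTensor(3.0 * data, frame_rate=4.0)
        p1, _ = stimulus_response_map(m1, [2])
        p2, _ = stimulus_response_map(m2, [2])
        np.testing.assert_allclose(p2, 3.0 * p1, rtol=1e-9)

    def test_stim_frame_out_of_range(self):
        movie = MovieTensor(np.zeros((5, 8, 8)), frame_rate=10.0)
        with pytest.raises(ValueError):
            stimulus_response_map(movie, [99])


class TestProfilesAndCameras:
    def test_bead_profile_printed_example(self):
        np.testing.assert_allclose(
            bead_profile_normalize([2.0, 4.0, 6.0]), [0.0, 0.5, 1.0]
        )

    def test_bead_profile_idempotent_and_affine_invariant(self, rng):
        prof = rng.random(50)
        once = bead_profile_normalize(prof)
        np.testing.assert_allclose(bead_profile_normalize(once), once, atol=1e-12)
        np.testing.assert_allclose(
            bead_profile_normalize(3.0 * prof - 7.0), once, atol=1e-12
        )

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError):
            bead_profile_normalize(np.ones(5))

    def test_cross_camera_gain_removed(self):
        signal = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        gains = np.array([1.0] * 3 + [10.0] * 3)
        cams = ["a"] * 3 + ["b"] * 3
        out = cross_camera_intensity_normalize(signal * gains, cams)
        np.testing.assert_allclose(out[:3], out[3:], atol=1e-12)

    def test_per_camera_mean_exactly_one(self, rng):
        vals = rng.uniform(1, 100, 12)
        cams = ["a", "b", "c"] * 4
        out = cross_camera_intensity_normalize(vals, cams)
        for cam in "abc":
            sel = np.array(cams) == cam
            assert out[sel].mean() == pytest.approx(1.0)
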