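import numpy as np
import pytest

from throughcuticle.core import (
    DomainError,
    ImageStack,
    InputError,
    ScenePhantom,
    Sphere,
    StimulusTimeline,
    Trace,
    TrackingError,
)
from throughcuticle.synthetic import make_calcium_movie, make_jitter_movie
from throughcuticle.traces import (
    average_frames,
    baseline_prestim,
    baseline_rolling,
    dff,
    disc_footprint,
    landmark_motion,
    median_filter_movie,
    peak_dff,
    register_translation,
    resample_spline,
    roi_trace,
    smooth_moving_mean,
)


def movie_of(data, rate=17.0):
    return ImageStack(np.asarray(data, dtype=float), frame_rate_hz=rate)


def trace_of(values, rate=4.25, stim=None):
    v = np.asarray(values, dtype=float)
    return Trace(np.arange(v.size) / rate, v, rate, stim_mask=stim)


class TestAverageFrames:
    @pytest.mark.parametrize("rate,k,expected", [(17.0, 4, 4.25), (6.5, 5, 1.3)])
    def test_effective_frame_rates(self, rng, rate, k, expected):
        movie = movie_of(rng.poisson(50.0, (20, 4, 4)), rate)
        assert average_frames(movie, k).frame_rate_hz == pytest.approx(expected)

    def test_identity_and_block_means(self, rng):
        movie = movie_of(rng.normal(0, 1, (9, 3, 3)))
        assert np.array_equal(average_frames(movie, 1).data, movie.data)
        out = average_frames(movie, 4)
        assert out.n_pages == 2  # trailing partial block dropped
        assert np.allclose(out.data[0], movie.data[:4].mean(axis=0))

    def test_k_larger_than_movie_rejected(self, rng):
        with pytest.raises(InputError):
            average_frames(movie_of(rng.normal(0, 1, (3, 2, 2))), 5)


class TestMedianFilter:
    def test_constant_frame_unchanged(self):
        movie = movie_of(np.full((2, 30, 30), 4.0))
        assert np.allclose(median_filter_movie(movie, 10).data, 4.0)

    def test_hot_pixel_removed(self):
        frame = np.full((25, 25), 2.0)
        frame[12, 12] = 1e6
        out = median_filter_movie(movie_of(frame[None]), 3).data[0]
        assert np.allclose(out, 2.0)

    def test_matches_bruteforce_disc_median(self, rng):
        """Agrees with an explicit neighborhood sort on random frames."""
        radius = 3
        frame = rng.normal(0, 1, (16, 16))
        out = median_filter_movie(movie_of(frame[None]), radius).data[0]
        foot = disc_footprint(radius)
        padded = np.pad(frame, radius, mode="symmetric")
        oracle = np.empty_like(frame)
        for i in range(16):
            for j in range(16):
                patch = padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1]
                oracle[i, j] = np.median(np.sort(patch[foot]))
        assert np.allclose(out, oracle)


class TestRoiTrace:
    def test_single_pixel_mask(self, rng):
        data = rng.normal(10, 1, (6, 5, 5))
        mask = np.zeros((5, 5), bool)
        mask[2, 3] = True
        tr = roi_trace(movie_of(data), mask)
        assert np.allclose(tr.values, data[:, 2, 3])

    def test_uniform_frames_and_loop_oracle(self, rng):
        data = rng.normal(10, 1, (4, 6, 6))
        mask = rng.random((6, 6)) > 0.5
        tr = roi_trace(movie_of(data), mask)
        oracle = [np.mean([data[t, i, j] for i in range(6) for j in range(6) if mask[i, j]])
                  for t in range(4)]
        assert np.allclose(tr.values, oracle)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(InputError):
            roi_trace(movie_of(rng.normal(0, 1, (3, 4, 4))), np.zeros((4, 4), bool))

    def test_frame_averaging_commutes_with_roi_trace(self, rng):
        data = rng.normal(50, 5, (16, 8, 8))
        mask = np.zeros((8, 8), bool)
        mask[2:5, 2:5] = True
        movie = movie_of(data)
        a = roi_trace(average_frames(movie, 4), mask).values
        b = roi_trace(movie, mask).values[:16].reshape(4, 4).mean(axis=1)
        assert np.allclose(a, b)


class TestBaselines:
    def test_prestim_constant_and_ramp(self):
        assert baseline_prestim(trace_of(np.full(30, 3.0)), onset_s=20 / 4.25) == 3.0
        ramp = trace_of(np.arange(1.0, 21.0), rate=1.0)
        # onset at sample 10 (t=10 s) -> mean of samples 0..9 = mean(1..10)
        assert baseline_prestim(ramp, onset_s=10.0) == pytest.approx(5.5)

    def test_prestim_insufficient_frames(self):
        with pytest.raises(InputError):
            baseline_prestim(trace_of(np.ones(30)), onset_s=3 / 4.25)

    def test_rolling_constant_any_mask(self):
        stim = np.zeros(40, bool)
        stim[10:20] = True
        tr = trace_of(np.full(40, 5.0), stim=stim)
        assert np.allclose(baseline_rolling(tr, 4.0), 5.0)

    def test_rolling_ignores_stimulus_step(self):
        # 20-sample trace at 1 Hz: step to 9 exactly during the stimulus
        values = np.ones(20)
        stim = np.zeros(20, bool)
        stim[8:12] = True
        values[8:12] = 9.0
        tr = Trace(np.arange(20.0), values, 1.0, stim_mask=stim)
        f0 = baseline_rolling(tr, window_s=5.0)
        assert np.allclose(f0, 1.0)

    def test_rolling_without_mask_matches_bruteforce_windows(self, rng):
        values = rng.normal(10, 2, 31)
        tr = Trace(np.arange(31.0), values, 1.0)
        w = 7
        f0 = baseline_rolling(tr, window_s=7.0)
        for i in range(31):
            lo, hi = max(0, i - w // 2), min(31, i + w // 2 + 1)
            assert f0[i] == pytest.approx(values[lo:hi].mean(), rel=1e-12)


class TestDff:
    def test_identity_and_doubling(self):
        tr = trace_of(np.full(10, 8.0))
        assert np.allclose(dff(tr, 8.0).values, 0.0)
        assert np.allclose(dff(tr, 4.0).values, 1.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(DomainError):
            dff(trace_of(np.ones(5)), 0.0)

    def test_invertible_to_1e12(self, rng):
        values = rng.uniform(5.0, 15.0, 50)
        f0 = rng.uniform(5.0, 10.0, 50)
        tr = trace_of(values)
        d = dff(tr, f0)
        recon = f0 * (1.0 + d.values)
        assert np.allclose(recon, values, rtol=0, atol=1e-12)


class TestSmoothingPeakResample:
    def test_moving_mean_impulse_response(self):
        d = dff(trace_of(np.concatenate([[2.0], np.ones(19)])), 1.0)
        out = smooth_moving_mean(d, 8)
        # impulse of height 1 spreads into 1/k over the trailing window
        expected = np.array([1.0 / (i + 1) for i in range(8)] + [0.0] * 12)
        assert np.allclose(out.values, expected)

    def test_window_one_is_identity(self, rng):
        d = dff(trace_of(rng.uniform(1, 2, 15)), 1.0)
        assert np.allclose(smooth_moving_mean(d, 1).values, d.values)

    def test_peak_dff_simple_cases(self):
        vals = np.zeros(40)
        vals[25] = 0.7
        d = dff(trace_of(1.0 + vals), 1.0)
        assert peak_dff(d, onset_s=20 / 4.25) == pytest.approx(0.7)
        assert peak_dff(dff(trace_of(np.ones(30)), 1.0), 1.0) == 0.0
        with pytest.raises(InputError):
            peak_dff(d, onset_s=100.0)

    def test_spline_exact_on_linear_ramp(self):
        tr = trace_of(np.linspace(0.0, 5.0, 30))
        out = resample_spline(tr, 5.0)
        assert np.allclose(out.values, out.times_s / tr.times_s[-1] * 5.0, atol=1e-10)

    def test_spline_sine_error_below_1e3(self):
        t = np.arange(0, 40.0, 1 / 4.25)
        tr = Trace(t, np.sin(2 * np.pi * 0.2 * t), 4.25)
        out = resample_spline(tr, 5.0)
        err = np.abs(out.values - np.sin(2 * np.pi * 0.2 * out.times_s))
        assert err.max() < 1e-3


class TestRegistration:
    def scene(self, rng):
        img = np.zeros((32, 32))
        img[10:18, 8:20] = rng.uniform(50, 100, (8, 12))
        return img

    def test_constructed_shift_recovered(self, rng):
        ref = self.scene(rng)
        shifted = np.roll(ref, (3, 0), axis=(0, 1))
        movie = movie_of(np.stack([ref, ref, shifted]))
        _, shifts = register_translation(movie)
        assert tuple(shifts[2]) == (-3, 0)
        assert tuple(shifts[1]) == (0, 0)

    def test_matches_exhaustive_shift_search(self, rng):
        ref = self.scene(rng)
        frame = np.roll(ref, (-2, 4), axis=(0, 1)) + rng.normal(0, 1, ref.shape)
        movie = movie_of(np.stack([ref, frame]))
        _, shifts = register_translation(movie)
        best, best_val = None, -np.inf
        for dr in range(-8, 9):
            for dc in range(-8, 9):
                val = np.sum(ref * np.roll(frame, (dr, dc), axis=(0, 1)))
                if val > best_val:
                    best, best_val = (dr, dc), val
        assert tuple(shifts[1]) == best


class TestLandmarkMotion:
    @staticmethod
    def mask_around(data, half=24):
        peak = np.unravel_index(np.argmax(data[0]), data.shape[1:])
        mask = np.zeros(data.shape[1:], bool)
        mask[peak[0] - half : peak[0] + half + 1, peak[1] - half : peak[1] + half + 1] = True
        return mask

    def test_static_spot(self):
        movie, _ = make_jitter_movie(1.0, 10, 0.0, 0.25, field_px=(96, 96), seed=0)
        disp, mean_disp, norm = landmark_motion(
            movie, self.mask_around(movie.data, 12), 0.25
        )
        assert np.allclose(disp, 0.0, atol=1e-9)
        assert mean_disp == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(norm, 0.0, atol=1e-12)

    def test_deterministic_fixed_step(self):
        movie, truth = make_jitter_movie(
            1.0, 20, 0.5, 0.5, field_px=(96, 96), displacement_model="fixed", seed=2
        )
        disp, mean_disp, _ = landmark_motion(
            movie, self.mask_around(movie.data, 12), 0.5
        )
        assert mean_disp == pytest.approx(0.5, rel=0.02)

    def test_rayleigh_jitter_recovers_scale_mean(self):
        """500 Rayleigh-jittered frames: tracked mean matches sigma*sqrt(pi/2)."""
        sigma = 1.0373
        movie, truth = make_jitter_movie(1.0, 500, sigma, 0.25, seed=1)
        disp, mean_disp, _ = landmark_motion(
            movie, self.mask_around(movie.data), 0.25
        )
        assert mean_disp == pytest.approx(truth["mean_displacement_um"], rel=0.01)
        assert mean_disp == pytest.approx(sigma * np.sqrt(np.pi / 2.0), rel=0.10)


class TestCalciumPipeline:
    layout = ScenePhantom((1, 32, 32), 1.0, 1.0, [Sphere((0.0, 16.0, 16.0), 6.0)])
    stim = StimulusTimeline([5.0], [3.0])

    def run_pipeline(self, amplitude, noise_sd, seed):
        movie, masks, truth = make_calcium_movie(
            self.layout, self.stim, amplitude=amplitude, duration_s=12.0,
            frame_rate_hz=17.0, noise_sd=noise_sd, seed=seed,
        )
        m4 = average_frames(movie, 4)
        tr = roi_trace(m4, masks[0])
        d = dff(tr, baseline_prestim(tr, 5.0))
        return peak_dff(d, 5.0)

    def test_amplitude_recovery_noiseless_within_10pct(self):
        assert self.run_pipeline(0.5, 0.0, 0) == pytest.approx(0.5, rel=0.10)

    def test_amplitude_recovery_noisy_within_20pct(self):
        for seed in range(20):
            assert self.run_pipeline(0.5, 0.05, seed) == pytest.approx(0.5, rel=0.20)

    def test_zero_amplitude_true_dff_is_zero(self):
        _, _, truth = make_calcium_movie(
            self.layout, self.stim, amplitude=0.0, duration_s=12.0, seed=0
        )
        assert np.allclose(truth["true_dff"][0], 0.0)
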