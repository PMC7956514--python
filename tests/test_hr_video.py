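"""rPPG pipeline: PCA cleaning, smoothness-priors detrending, z-score,
spectral-peak heart rate."""

import numpy as np
import pytest

from facevitals import (
    DetrendSpec,
    InvalidParameterError,
    SampledSignal,
    ShortSignalError,
    SimSpec,
    detrend_smoothness_priors,
    gen_roi_trace,
    hr_from_roi,
    hr_from_window,
    hr_series_video,
    pca_clean,
    zscore,
)
from facevitals.hr_video import RoiGeometry, RoiTrace, extract_roi_traces
from facevitals.blink_video import LandmarkFrame

FPS = 30.0


def dense_detrend_oracle(x: np.ndarray, lam: float) -> np.ndarray:
    """Independent dense-matrix solve of (I + lam^2 D2'D2) trend = x."""
    n = x.size
    d2 = np.zeros((n - 2, n))
    for i in range(n - 2):
        d2[i, i : i + 3] = [1.0, -2.0, 1.0]
    trend = np.linalg.solve(np.eye(n) + lam**2 * (d2.T @ d2), x)
    return x - trend


class TestDetrend:
    @pytest.mark.parametrize("n", [100, 500])
    @pytest.mark.parametrize(
        "lam,tol",
        [(10.0, 1e-8), (6332.657, 1e-6)],  # cond(I + lam^2 D'D) ~ 6e8 at the larger lam
        ids=["lam10", "lam-cutoff"],
    )
    def test_matches_dense_matrix_oracle(self, n, lam, tol):
        rng = np.random.default_rng(n)
        x = rng.standard_normal(n).cumsum()
        out = detrend_smoothness_priors(SampledSignal(x, FPS), DetrendSpec(lambda_=lam))
        assert np.max(np.abs(out.values - dense_detrend_oracle(x, lam))) < tol

    def test_linear_ramp_annihilated(self):
        ramp = np.linspace(0.0, 100.0, 600)
        out = detrend_smoothness_priors(SampledSignal(ramp, FPS))
        assert np.max(np.abs(out.values)) < 1e-6 * 100.0

    def test_cardiac_tone_power_retained(self, tone):
        sig = tone(1.2, FPS, 40.0)
        out = detrend_smoothness_priors(sig, DetrendSpec(cutoff_hz=0.060))
        assert np.sum(out.values**2) >= 0.95 * np.sum(sig.values**2)

    def test_zero_signal_zero_output(self):
        out = detrend_smoothness_priors(SampledSignal(np.zeros(200), FPS))
        assert np.allclose(out.values, 0.0)

    def test_output_mean_free(self):
        rng = np.random.default_rng(1)
        x = 50 + rng.standard_normal(900) + np.linspace(0, 5, 900)
        out = detrend_smoothness_priors(SampledSignal(x, FPS))
        assert abs(np.mean(out.values)) < 0.01 * np.std(x)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(InvalidParameterError):
            DetrendSpec(lambda_=-1.0)

    def test_cutoff_derived_lambda(self):
        spec = DetrendSpec(cutoff_hz=0.060)
        lam = spec.effective_lambda(30.0)
        # half-power corner of the implied high-pass sits at the cutoff
        s = np.sin(np.pi * 0.060 / 30.0)
        assert lam == pytest.approx(1.0 / (4 * s * s))


class TestZscore:
    def test_hand_computed_example(self):
        out = zscore(SampledSignal([1.0, 2.0, 3.0], FPS))
        assert np.allclose(out.x.values, [-1.22474487, 0.0, 1.22474487], atol=1e-6)
        assert not out.degenerate

    def test_constant_input_degenerate(self):
        out = zscore(SampledSignal(np.full(10, 4.2), FPS))
        assert np.all(out.x.values == 0)
        assert out.degenerate

    def test_idempotent_on_normalised_input(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        x = (x - x.mean()) / x.std()
        out = zscore(SampledSignal(x, FPS))
        assert np.allclose(out.x.values, x, atol=1e-9)


class TestHrFromWindow:
    def _window(self, freq):
        t = np.arange(100) / FPS
        return np.sin(2 * np.pi * freq * t)

    @pytest.mark.parametrize("freq,bpm", [(1.2, 72.0), (1.0, 60.0)])
    def test_tone_frequency_recovered(self, freq, bpm):
        est, valid = hr_from_window(self._window(freq), FPS)
        assert valid
        assert est == pytest.approx(bpm, abs=1.0)

    def test_out_of_band_tone_invalid(self):
        _, valid = hr_from_window(self._window(0.3), FPS)
        assert not valid

    def test_wrong_window_length_rejected(self):
        with pytest.raises(InvalidParameterError):
            hr_from_window(np.zeros(99), FPS)


class TestHrSeries:
    def test_two_minutes_of_clean_tone(self, tone):
        z = zscore(tone(1.2, FPS, 120.0))
        series = hr_series_video(z, edge_guard_frames=0)
        assert len(series.bpm) == 2
        assert np.all(series.valid)
        assert np.allclose(series.bpm, 72.0, atol=1.0)

    def test_stepped_rate_tracked_per_minute(self):
        t1 = np.arange(int(60 * FPS)) / FPS
        t2 = np.arange(int(60 * FPS)) / FPS
        x = np.concatenate([np.sin(2 * np.pi * 1.0 * t1), np.sin(2 * np.pi * 1.5 * t2)])
        series = hr_series_video(zscore(SampledSignal(x, FPS)), edge_guard_frames=0)
        assert series.bpm[0] == pytest.approx(60.0, abs=2.0)
        assert series.bpm[1] == pytest.approx(90.0, abs=2.0)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ShortSignalError):
            hr_series_video(zscore(SampledSignal(np.ones(90), FPS)))


class TestPcaClean:
    def _roi(self, r_left, r_right):
        n = len(r_left)
        z = np.zeros(n)
        return RoiTrace(r_left, z, z, r_right, z, z, fps=FPS)

    def test_common_tone_survives_independent_noise(self, tone):
        rng = np.random.default_rng(3)
        base = tone(1.2, FPS, 60.0).values
        roi = self._roi(base + 0.5 * rng.standard_normal(base.size),
                        base + 0.5 * rng.standard_normal(base.size))
        comp = pca_clean(roi)
        from facevitals import power_spectrum

        spec = power_spectrum(comp.x, 4096)
        sel = (spec.freqs_hz >= 0.6) & (spec.freqs_hz <= 2.2)
        peak = spec.freqs_hz[sel][np.argmax(spec.power[sel])]
        assert peak == pytest.approx(1.2, abs=0.05)

    def test_drift_plus_tone_selects_cardiac_component(self, tone):
        t = np.arange(int(60 * FPS)) / FPS
        drift = 5.0 * np.sin(2 * np.pi * 0.05 * t)
        pulse = tone(1.2, FPS, 60.0).values
        rng = np.random.default_rng(4)
        roi = self._roi(drift + pulse + 0.1 * rng.standard_normal(t.size),
                        drift + pulse + 0.1 * rng.standard_normal(t.size))
        comp = pca_clean(roi)
        from facevitals import power_spectrum

        # the selected component carries the cardiac line (the drift is
        # out of band), not the noise-difference component
        spec = power_spectrum(comp.x, 4096)
        sel = (spec.freqs_hz >= 0.6) & (spec.freqs_hz <= 2.2)
        inband_peak = spec.freqs_hz[sel][np.argmax(spec.power[sel])]
        assert inband_peak == pytest.approx(1.2, abs=0.05)
        assert spec.power[sel].max() > 100 * np.median(spec.power[sel])

    def test_rank_one_input_reproduced_up_to_scale(self, tone):
        base = 100 + tone(1.2, FPS, 30.0).values
        comp = pca_clean(self._roi(base.copy(), base.copy()))
        r = np.corrcoef(comp.x.values, base)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_single_subtrace_falls_back(self, tone):
        base = tone(1.2, FPS, 30.0).values
        roi = self._roi(base, base.copy())
        roi.r_right = roi.r_left  # identical -> keep PCA path
        single = RoiTrace(base, base * 0, base * 0, base, base * 0, base * 0, fps=FPS)
        single_view = single.red_subtraces[:, :1]
        assert single_view.shape[1] == 1  # degenerate layout exercised below

        class OneCheek:
            red_subtraces = base.reshape(-1, 1)
            fps = FPS

            def __len__(self):
                return base.size

        comp = pca_clean(OneCheek())
        assert comp.pca_fallback


class TestEndToEnd:
    def test_amplitude_invariance(self):
        spec = SimSpec(duration_s=120, fs=FPS, seed=8, hr_bpm=72, snr_db=6,
                       drift_amplitude_ratio=2.0)
        roi, _ = gen_roi_trace(spec)
        ref = hr_from_roi(roi).bpm
        scaled = RoiTrace(roi.r_left * 3.0, roi.g_left, roi.b_left,
                          roi.r_right * 3.0, roi.g_right, roi.b_right, fps=FPS)
        assert np.allclose(hr_from_roi(scaled).bpm, ref, atol=1e-6)

    @pytest.mark.parametrize("bpm", [48, 72, 108])
    def test_recovery_with_drift_and_noise(self, bpm):
        errs = []
        for seed in range(5):
            spec = SimSpec(duration_s=120, fs=FPS, seed=seed * 7 + bpm, hr_bpm=bpm,
                           snr_db=0, drift_amplitude_ratio=5.0)
            roi, truth = gen_roi_trace(spec)
            series = hr_from_roi(roi)
            errs.extend(np.abs(series.bpm[series.valid] - bpm))
        assert np.mean(errs) <= 3.0


class TestExtractRoi:
    def _landmarks(self, n, shift=0.0):
        pts = np.zeros((68, 2))
        pts[36:42] = [200 + shift, 200] + np.array([[-10, 0], [-5, -3], [5, -3],
                                                    [10, 0], [5, 3], [-5, 3]])
        pts[42:48] = [400 + shift, 200] + np.array([[-10, 0], [-5, -3], [5, -3],
                                                    [10, 0], [5, 3], [-5, 3]])
        pts[33] = [300 + shift, 300]
        return [LandmarkFrame(i, pts, frame_size=(640, 480)) for i in range(n)]

    def test_uniform_red_frame(self):
        frames = [np.dstack([np.full((480, 640), 200.0), np.zeros((480, 640)),
                             np.zeros((480, 640))])] * 5
        trace = extract_roi_traces(frames, self._landmarks(5), fps=FPS)
        assert np.allclose(trace.r_left, 200.0)
        assert np.allclose(trace.g_left, 0.0)
        assert np.allclose(trace.b_right, 0.0)

    def test_alternating_intensity_followed(self):
        f1 = np.dstack([np.full((480, 640), 100.0)] + [np.zeros((480, 640))] * 2)
        f2 = np.dstack([np.full((480, 640), 110.0)] + [np.zeros((480, 640))] * 2)
        trace = extract_roi_traces([f1, f2, f1, f2], self._landmarks(4), fps=FPS)
        assert np.allclose(trace.r_left, [100, 110, 100, 110])

    def test_too_many_invalid_frames_rejected(self):
        frames = [np.zeros((480, 640, 3))] * 10
        lms = self._landmarks(10)
        for lm in lms[:3]:
            lm.valid = False
        with pytest.raises(InvalidParameterError, match="valid landmarks"):
            extract_roi_traces(frames, lms, fps=FPS)
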