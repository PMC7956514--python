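"""Filter contracts, spectral utilities and CSV round-trips."""

import numpy as np
import pytest
from scipy import signal as sps

from facevitals import (
    BandpassSpec,
    InvalidParameterError,
    NonUniformSamplingError,
    ParseError,
    SampledSignal,
    ShortSignalError,
    bandpass,
    power_spectrum,
    read_events_csv,
    read_signal_csv,
    write_events_csv,
    write_signal_csv,
)
from facevitals.core_signals import design_fir_taps, fir_transient_guard_s, interpolate_gaps

from conftest import steady_state_amplitude

FIR_PULSE = BandpassSpec(0.6, 2.2, 128, "hamming_fir")
IIR_EOG = BandpassSpec(2.0, 10.0, 5, "butterworth")


class TestBandpass:
    def test_dc_removed_by_any_passband(self):
        sig = SampledSignal(np.full(3000, 5.0), 30.0)
        out = bandpass(sig, FIR_PULSE)
        trim = FIR_PULSE.order // 2  # ceil of the (taps-1)/2 group delay
        assert np.max(np.abs(out.values[trim:-trim])) < 1e-6

    @pytest.mark.parametrize(
        "freq,lo,hi",
        [(1.2, 0.9, 1.1), (5.0, 0.0, 0.1)],
        ids=["passband", "stopband"],
    )
    def test_fir_tone_amplitudes_match_design(self, tone, freq, lo, hi):
        # oracle: the designed filter's own frequency response
        taps = design_fir_taps(FIR_PULSE, 30.0)
        w, h = sps.freqz(taps, worN=8192, fs=30.0)
        design_gain = np.abs(h[np.argmin(np.abs(w - freq))])
        assert lo <= design_gain <= hi

        out = bandpass(tone(freq, 30.0, 60.0), FIR_PULSE)
        amp = steady_state_amplitude(out.values, edge_trim=300)
        assert lo <= amp <= hi

    def test_butterworth_band_gains(self, tone):
        sig_in = tone(5.0, 256.0, 30.0)  # inside 2-10 Hz
        sig_out = tone(0.5, 256.0, 30.0)  # below the band
        inband = steady_state_amplitude(bandpass(sig_in, IIR_EOG).values, 512)
        outband = steady_state_amplitude(bandpass(sig_out, IIR_EOG).values, 512)
        assert 0.9 <= inband <= 1.1
        assert outband < 0.1

    def test_zero_phase_no_lag(self, tone):
        sig = tone(5.0, 256.0, 20.0)
        out = bandpass(sig, IIR_EOG)
        xc = np.correlate(out.values, sig.values, mode="full")
        lag = int(np.argmax(xc)) - (len(sig) - 1)
        assert lag == 0

    def test_linearity(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(4000)
        y = rng.standard_normal(4000)
        a, b = 2.5, -1.25
        fs = 256.0
        lhs = bandpass(SampledSignal(a * x + b * y, fs), IIR_EOG).values
        rhs = a * bandpass(SampledSignal(x, fs), IIR_EOG).values + b * bandpass(
            SampledSignal(y, fs), IIR_EOG
        ).values
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_band_edge_at_nyquist_rejected(self, tone):
        sig = tone(1.0, 30.0, 10.0)
        with pytest.raises(InvalidParameterError):
            bandpass(sig, BandpassSpec(2.0, 15.0, 5, "butterworth"))

    def test_short_signal_rejected_not_truncated(self):
        sig = SampledSignal(np.zeros(20), 256.0)
        with pytest.raises(ShortSignalError):
            bandpass(sig, IIR_EOG)

    def test_fir_transient_guard(self):
        assert fir_transient_guard_s(FIR_PULSE, 30.0) == pytest.approx(63.5 / 30.0)
        with pytest.raises(InvalidParameterError):
            fir_transient_guard_s(IIR_EOG, 256.0)


class TestPowerSpectrum:
    def test_single_tone_argmax(self, tone):
        sig = tone(1.0, 30.0, 10.0)
        spec = power_spectrum(sig, 1024)
        assert abs(spec.peak_hz() - 1.0) <= spec.resolution_hz

    @pytest.mark.parametrize("n_fft_factor", [4, 8])
    def test_tone_argmax_within_one_bin_when_padded(self, tone, n_fft_factor):
        sig = tone(2.7, 30.0, 8.0)
        n_fft = n_fft_factor * len(sig)
        spec = power_spectrum(sig, n_fft)
        assert abs(spec.peak_hz() - 2.7) <= spec.resolution_hz

    def test_parseval(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(999)
        sig = SampledSignal(x, 30.0)
        spec = power_spectrum(sig, 2048)
        assert np.sum(spec.power) == pytest.approx(np.sum(x**2), rel=1e-9)
        # and within 10% of variance x N for zero-mean noise
        assert np.sum(spec.power) == pytest.approx(np.var(x) * len(x), rel=0.1)

    def test_zeros_have_zero_power(self):
        spec = power_spectrum(SampledSignal(np.zeros(100), 30.0), 128)
        assert np.all(spec.power == 0)

    def test_n_fft_shorter_than_signal_rejected(self):
        with pytest.raises(InvalidParameterError):
            power_spectrum(SampledSignal(np.zeros(100), 30.0), 64)


class TestCsvIO:
    def test_signal_roundtrip(self, tmp_path):
        ramp = SampledSignal(np.linspace(0, 1, 2560), 256.0)
        p = tmp_path / "sig.csv"
        write_signal_csv(ramp, str(p))
        back = read_signal_csv(str(p), fs=256.0)
        assert np.allclose(back.values, ramp.values, atol=1e-9)
        assert back.fs == ramp.fs

    def test_timed_roundtrip_infers_rate(self, tmp_path):
        sig = SampledSignal(np.arange(100.0), 30.0, t0=2.0)
        p = tmp_path / "sig.csv"
        write_signal_csv(sig, str(p), include_time=True)
        back = read_signal_csv(str(p))
        assert back.fs == pytest.approx(30.0)
        assert back.t0 == pytest.approx(2.0)
        assert np.allclose(back.values, sig.values)

    def test_header_only_file_is_empty_signal_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("value\n")
        with pytest.raises(ShortSignalError):
            read_signal_csv(str(p), fs=30.0)

    def test_missing_value_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("foo\n1\n")
        with pytest.raises(ParseError):
            read_signal_csv(str(p), fs=30.0)

    def test_non_numeric_cell_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("value\n1.0\noops\n3.0\n")
        with pytest.raises(ParseError, match="row 3"):
            read_signal_csv(str(p), fs=30.0)

    def test_jittered_time_column_rejected(self, tmp_path):
        t = np.arange(50) / 30.0
        t[25] += 0.02 * (1 / 30.0)
        lines = ["time,value"] + [f"{ti},{i}" for i, ti in enumerate(t)]
        p = tmp_path / "jitter.csv"
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(NonUniformSamplingError):
            read_signal_csv(str(p))

    def test_events_roundtrip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame({"t_peak_s": [0.5, 1.25], "amplitude": [3.0, 2.5]})
        p = tmp_path / "events.csv"
        write_events_csv(df, str(p))
        back = read_events_csv(str(p))
        assert np.allclose(back["t_peak_s"], df["t_peak_s"])


class TestPropertyBased:
    """Randomised invariants (derandomised for reproducibility)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra import numpy as hnp

    finite_traces = hnp.arrays(
        dtype=float,
        shape=st.integers(min_value=64, max_value=256),
        elements=st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
    )

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(x=finite_traces)
    def test_parseval_holds_for_any_finite_trace(self, x):
        spec = power_spectrum(SampledSignal(x, 30.0), 512)
        assert np.sum(spec.power) == pytest.approx(np.sum(x**2), rel=1e-9, abs=1e-9)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(x=finite_traces, scale=st.floats(min_value=0.25, max_value=8.0))
    def test_bandpass_homogeneity(self, x, scale):
        sig = SampledSignal(x, 30.0)
        spec = BandpassSpec(1.0, 3.0, 2, "butterworth")
        ref = bandpass(sig, spec).values
        scaled = bandpass(SampledSignal(scale * x, 30.0), spec).values
        assert np.allclose(scaled, scale * ref, rtol=1e-9, atol=1e-6)


class TestInterpolateGaps:
    def test_linear_fill(self):
        out = interpolate_gaps(np.array([4.0, 0.0, 6.0]), np.array([True, False, True]))
        assert out[1] == pytest.approx(5.0)

    def test_all_invalid_rejected(self):
        with pytest.raises(InvalidParameterError):
            interpolate_gaps(np.zeros(3), np.zeros(3, dtype=bool))


class TestSampledSignal:
    def test_invariants_enforced(self):
        with pytest.raises(InvalidParameterError):
            SampledSignal([1.0, np.nan], 30.0)
        with pytest.raises(InvalidParameterError):
            SampledSignal([1.0], 0.0)
        with pytest.raises(InvalidParameterError):
            SampledSignal([], 30.0)

    def test_duration(self):
        assert SampledSignal(np.zeros(90), 30.0).duration_s == pytest.approx(3.0)
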