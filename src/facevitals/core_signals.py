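"""Shared signal containers, CSV I/O and digital-filter primitives.

Every pipeline in this package works on uniformly sampled scalar traces:
256 Hz biosignals (ECG, vertical EOG) and 30 fps video-derived traces
(eyelid distance, cheek-ROI colour means).  This module holds the common
currency — :class:`SampledSignal` — together with the band-pass filters
(zero-phase Butterworth IIR and linear-phase Hamming-window FIR), a
one-sided FFT power spectrum, and the plain-CSV readers/writers used by
the command-line tools.

Filtering is offline and zero-phase throughout: recordings are analysed
after the fact, and preserving event timing matters for blink and R-peak
localisation.  The IIR path runs forward–backward over second-order
sections; the FIR path exploits the symmetry of windowed-sinc taps and
compensates the integer group delay of a single pass, which keeps the
designed magnitude response exactly (a forward–backward pass would
square it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sps

__all__ = [
    "SignalError",
    "InvalidParameterError",
    "ShortSignalError",
    "ParseError",
    "NonUniformSamplingError",
    "SampledSignal",
    "BandpassSpec",
    "Spectrum",
    "bandpass",
    "fir_transient_guard_s",
    "power_spectrum",
    "read_signal_csv",
    "write_signal_csv",
    "read_events_csv",
    "write_events_csv",
    "interpolate_gaps",
]


class SignalError(ValueError):
    """Base class for signal-processing contract violations."""


class InvalidParameterError(SignalError):
    """A filter or analysis parameter is outside its valid range."""


class ShortSignalError(SignalError):
    """The signal is too short for the requested operation."""


class ParseError(SignalError):
    """A CSV file violates the expected layout; names the offending row."""


class NonUniformSamplingError(ParseError):
    """A time column's sampling interval jitters by more than 1%."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SampledSignal:
    """A uniformly sampled scalar trace.

    Parameters
    ----------
    values : array-like
        Sample values, arbitrary units. Must be finite and non-empty.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Start time of the first sample in seconds.
    label : str
        Free-text description carried through the pipelines.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise InvalidParameterError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("values must be finite")
        if not (self.fs > 0):
            raise InvalidParameterError(f"fs must be > 0, got {self.fs}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    def with_values(self, values: np.ndarray, label: str | None = None) -> "SampledSignal":
        """Same sampling metadata, new sample values."""
        return SampledSignal(values, self.fs, self.t0, self.label if label is None else label)


@dataclass(frozen=True)
class BandpassSpec:
    """Band-pass filter description.

    ``family`` selects a Butterworth IIR (``order`` = analogue prototype
    order, applied zero-phase over second-order sections) or a
    Hamming-window FIR (``order`` = number of taps).
    """

    low_hz: float
    high_hz: float
    order: int
    family: str = "butterworth"

    def __post_init__(self) -> None:
        if self.family not in ("butterworth", "hamming_fir"):
            raise InvalidParameterError(f"unknown filter family {self.family!r}")
        if self.order < 1:
            raise InvalidParameterError("order must be >= 1")
        if not (0 < self.low_hz < self.high_hz):
            raise InvalidParameterError(
                f"need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})"
            )


@dataclass
class Spectrum:
    """One-sided power spectrum on a uniform frequency grid."""

    freqs_hz: np.ndarray
    power: np.ndarray
    resolution_hz: float

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs_hz.shape != self.power.shape:
            raise InvalidParameterError("freqs_hz and power must have equal length")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise InvalidParameterError("freqs_hz must be strictly increasing")
        if np.any(self.power < -1e-12):
            raise InvalidParameterError("power must be non-negative")

    def peak_hz(self) -> float:
        return float(self.freqs_hz[int(np.argmax(self.power))])


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def _design_sos(spec: BandpassSpec, fs: float) -> np.ndarray:
    return _sps.butter(spec.order, [spec.low_hz, spec.high_hz], btype="band", fs=fs, output="sos")


def design_fir_taps(spec: BandpassSpec, fs: float) -> np.ndarray:
    """Windowed-sinc band-pass taps (Hamming window, ``spec.order`` taps).

    The taps are shifted to an exactly zero DC sum so a constant input
    maps to zero; the shift is ~1e-5 per tap and leaves the band-pass
    response unchanged to ~1e-3 absolute.
    """
    taps = _sps.firwin(
        spec.order, [spec.low_hz, spec.high_hz], fs=fs, window="hamming", pass_zero=False
    )
    return taps - taps.mean()


def fir_transient_guard_s(spec: BandpassSpec, fs: float) -> float:
    """Duration of the edge region affected by FIR start-up transients.

    The first and last ``(taps - 1) / 2`` samples of a delay-compensated
    FIR output mix with the implicit zero padding; downstream threshold
    computations exclude them.
    """
    if spec.family != "hamming_fir":
        raise InvalidParameterError("transient guard is defined for hamming_fir only")
    return ((spec.order - 1) / 2) / fs


def bandpass(signal: SampledSignal, spec: BandpassSpec) -> SampledSignal:
    """Zero-phase band-pass filtering.

    Butterworth filters run forward–backward over second-order sections
    (numerically stable for narrow bands at 256 Hz); Hamming FIR filters
    run as a single convolution with the symmetric taps, group delay
    compensated, so the designed magnitude response applies unsquared.

    Raises
    ------
    InvalidParameterError
        If a band edge is at or above the Nyquist frequency.
    ShortSignalError
        If the signal is too short for stable zero-phase application.
    """
    nyq = signal.fs / 2.0
    if not (0 < spec.low_hz < spec.high_hz < nyq):
        raise InvalidParameterError(
            f"band ({spec.low_hz}, {spec.high_hz}) Hz must lie strictly inside (0, {nyq}) Hz"
        )
    x = signal.values
    if spec.family == "butterworth":
        sos = _design_sos(spec, signal.fs)
        padlen = 3 * (2 * sos.shape[0] + 1)  # sosfiltfilt default
        if len(x) <= max(3 * spec.order, padlen):
            raise ShortSignalError(
                f"signal of {len(x)} samples too short for zero-phase IIR "
                f"(need > {max(3 * spec.order, padlen)})"
            )
        y = _sps.sosfiltfilt(sos, x)
    else:
        taps = design_fir_taps(spec, signal.fs)
        if len(x) < len(taps):
            raise ShortSignalError(
                f"signal of {len(x)} samples shorter than the {len(taps)}-tap FIR"
            )
        y = np.convolve(x, taps, mode="same")
    return signal.with_values(y)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def power_spectrum(signal: SampledSignal, n_fft: int) -> Spectrum:
    """One-sided FFT power spectrum, zero-padded to ``n_fft``.

    Normalisation: ``sum(power) == sum(x**2)`` exactly (discrete
    Parseval identity; DC and Nyquist bins enter once, all others
    twice).  Zero padding refines the grid without adding power.
    """
    x = signal.values
    if x.size == 0:
        raise ShortSignalError("empty signal")
    if n_fft < x.size:
        raise InvalidParameterError(f"n_fft ({n_fft}) must be >= signal length ({x.size})")
    spec = np.fft.rfft(x, n_fft)
    power = np.abs(spec) ** 2 / n_fft
    scale = np.full(power.shape, 2.0)
    scale[0] = 1.0
    if n_fft % 2 == 0:
        scale[-1] = 1.0
    power *= scale
    freqs = np.fft.rfftfreq(n_fft, 1.0 / signal.fs)
    return Spectrum(freqs, power, resolution_hz=signal.fs / n_fft)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------
# Dialect: comma-separated, UTF-8, '.' decimal, mandatory header row.


def _numeric_column(df: pd.DataFrame, name: str, path: str) -> np.ndarray:
    col = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(col))
    if bad.size:
        # +2: header line plus 1-based numbering
        raise ParseError(f"{path}: non-numeric value in column {name!r} at row {bad[0] + 2}")
    return col


def read_signal_csv(path: str, fs: float | None = None) -> SampledSignal:
    """Read a trace from CSV.

    Accepts either a single ``value`` column (sampling rate must then be
    supplied) or ``time,value`` columns with a uniform time grid (the
    rate is inferred; jitter beyond 1% of the sampling interval is an
    error).
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if "value" not in cols:
        raise ParseError(f"{path}: missing required column 'value' (found {cols})")
    if len(df) == 0:
        raise ShortSignalError(f"{path}: file contains a header but no samples")
    values = _numeric_column(df, "value", path)
    if "time" in cols:
        t = _numeric_column(df, "time", path)
        if len(t) < 2:
            raise ShortSignalError(f"{path}: need at least 2 samples to infer the rate")
        dt = np.diff(t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise ParseError(f"{path}: non-monotone time column at row {bad[0] + 3}")
        dt0 = float(np.median(dt))
        if np.any(np.abs(dt - dt0) > 0.01 * dt0):
            raise NonUniformSamplingError(
                f"{path}: time column jitter exceeds 1% of the sampling interval"
            )
        inferred = 1.0 / dt0
        if fs is not None and abs(inferred - fs) > 0.01 * fs:
            raise InvalidParameterError(
                f"{path}: time column implies fs={inferred:.6g} Hz, caller said {fs} Hz"
            )
        return SampledSignal(values, inferred, t0=float(t[0]))
    if fs is None:
        raise InvalidParameterError(f"{path}: single-column CSV requires an explicit fs")
    return SampledSignal(values, fs)


def write_signal_csv(signal: SampledSignal, path: str, include_time: bool = False) -> None:
    if include_time:
        df = pd.DataFrame({"time": signal.times, "value": signal.values})
    else:
        df = pd.DataFrame({"value": signal.values})
    df.to_csv(path, index=False, float_format="%.12g")


def read_events_csv(path: str) -> pd.DataFrame:
    """Read a detected-event table (columns ``t_peak_s``, ``amplitude``,
    optionally ``correlation``)."""
    df = pd.read_csv(path)
    for name in ("t_peak_s", "amplitude"):
        if name not in df.columns:
            raise ParseError(f"{path}: missing required column {name!r}")
        if len(df):
            df[name] = _numeric_column(df, name, path)
    return df


def write_events_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# small helpers
# ---------------------------------------------------------------------------


def interpolate_gaps(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linearly interpolate samples flagged invalid (edges held constant)."""
    values = np.asarray(values, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        raise InvalidParameterError("no valid samples to interpolate from")
    idx = np.arange(values.size)
    out = values.copy()
    out[~valid] = np.interp(idx[~valid], idx[valid], values[valid])
    return out
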