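"""Ground-truth signal generators for every pipeline input.

These generators emulate the acquisition set-up the pipelines expect —
256 Hz biosignals and 30 fps video-derived traces — and return the
ground truth (beat times, blink times, per-minute heart rate) alongside
the data, so every downstream test is self-scoring.  All generators are
deterministic under a fixed seed.

Signal-to-noise convention: ``snr_db`` is the power ratio of the
*signal component* (the QRS train, the blink deflections, the pulse
oscillation) to the additive noise, in dB.  Sparse event signals
therefore get amplitudes well above the noise floor at a given
``snr_db``, matching how such recordings look in practice.

Noise models:

* ECG — additive white Gaussian noise (broadband EMG/electrode noise).
* EOG — additive white Gaussian noise (background EEG at Fpz).
* eyelid distance — 80% (power) slow drift, an AR(1) process with
  coefficient 0.99 emulating head/gaze motion, plus 20% white
  per-frame landmark jitter.
* cheek ROI — common low-frequency illumination drift (three random
  sinusoids in 0.02–0.1 Hz, amplitude ``drift_amplitude_ratio`` × the
  pulse amplitude) shared by both cheeks and all channels, plus
  independent white noise per cheek.

Blink times follow a Poisson process thinned to a 500 ms minimum
inter-blink interval (physiological refractory), redrawn until at least
one event falls in the trace — an awake subject at the supported rates
always blinks within a minute.  The pulse waveform carries a second
harmonic at 30% amplitude so spectral HR pickers are exercised against
harmonic confusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sps

from .blink_video import EyelidTrace
from .core_signals import InvalidParameterError, SampledSignal
from .hr_video import RoiTrace

__all__ = [
    "SimSpec",
    "gen_ecg",
    "gen_eog",
    "gen_eyelid_trace",
    "gen_roi_trace",
]


@dataclass(frozen=True)
class SimSpec:
    """Conditions of one simulated recording.

    ``hr_bpm`` and ``blink_rate_per_min`` may be scalars (constant) or
    per-minute sequences (piecewise-constant truth).  ``snr_db=None``
    disables noise.
    """

    duration_s: float
    fs: float
    seed: int = 0
    hr_bpm: object = None
    blink_rate_per_min: object = None
    snr_db: float | None = None
    drift_amplitude_ratio: float = 0.0
    rr_jitter: float = 0.0  # fractional RR jitter (<= 0.03 typical)
    blink_duration_range_s: tuple[float, float] = (0.15, 0.30)
    blink_amplitude_jitter: float = 0.2
    eyelid_baseline_px: float = 6.0
    eyelid_blink_depth_px: float = 5.0
    roi_base_level: float = 120.0
    roi_pulse_amplitude: float = 1.0
    edge_margin_s: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise InvalidParameterError("duration must be positive")
        if self.fs <= 0:
            raise InvalidParameterError("fs must be positive")

    def hr_for_minute(self, minute: int) -> float:
        hr = np.atleast_1d(np.asarray(self.hr_bpm, dtype=float))
        return float(hr[min(minute, hr.size - 1)])

    def rate_for_minute(self, minute: int) -> float:
        r = np.atleast_1d(np.asarray(self.blink_rate_per_min, dtype=float))
        return float(r[min(minute, r.size - 1)])


def _rng(spec: SimSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


def _noise_sigma(component: np.ndarray, snr_db: float, fallback_power: float) -> float:
    p = float(np.mean(component**2))
    if p == 0:
        p = fallback_power
    return float(np.sqrt(p / 10 ** (snr_db / 10.0)))


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

HR_RANGE = (40.0, 180.0)


def _gauss(t: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sd) ** 2)


def gen_ecg(spec: SimSpec) -> tuple[SampledSignal, np.ndarray]:
    """Synthetic single-lead ECG and its true R-peak times.

    Each beat is a stereotyped PQRST complex (Gaussian bumps: upright
    R spike of unit amplitude, smaller Q/S deflections, P and T waves);
    RR intervals follow the per-minute ``hr_bpm`` truth with optional
    fractional jitter.
    """
    if spec.hr_bpm is None:
        raise InvalidParameterError("gen_ecg requires hr_bpm")
    hr = np.atleast_1d(np.asarray(spec.hr_bpm, dtype=float))
    if np.any(hr < HR_RANGE[0]) or np.any(hr > HR_RANGE[1]):
        raise InvalidParameterError(f"hr_bpm outside the supported range {HR_RANGE}")
    if spec.fs < 128:
        raise InvalidParameterError("gen_ecg needs fs >= 128 Hz")
    rng = _rng(spec)
    beats = []
    t = spec.edge_margin_s / 2
    while t < spec.duration_s - spec.edge_margin_s / 2:
        beats.append(t)
        rr = 60.0 / spec.hr_for_minute(int(t // 60))
        if spec.rr_jitter:
            rr *= 1.0 + spec.rr_jitter * rng.uniform(-1, 1)
        t += rr
    beats = np.asarray(beats)
    n = int(round(spec.duration_s * spec.fs))
    x = np.zeros(n)
    waves = (  # (amplitude, offset_s, width_s) of the PQRST bumps
        (0.15, -0.18, 0.04),
        (-0.15, -0.022, 0.008),
        (1.00, 0.0, 0.009),
        (-0.20, 0.025, 0.009),
        (0.35, 0.28, 0.06),
    )
    for b in beats:
        for amp, off, sd in waves:
            # evaluate each bump only on its +-5 sigma support
            i0 = max(0, int((b + off - 5 * sd) * spec.fs))
            i1 = min(n, int((b + off + 5 * sd) * spec.fs) + 1)
            tt = np.arange(i0, i1) / spec.fs
            x[i0:i1] += amp * _gauss(tt, b + off, sd)
    if spec.snr_db is not None:
        sigma = _noise_sigma(x, spec.snr_db, fallback_power=0.05)
        x = x + sigma * rng.standard_normal(n)
    return SampledSignal(x, spec.fs, label="synthetic ECG"), beats


# ---------------------------------------------------------------------------
# blink-time process (shared by EOG and eyelid traces)
# ---------------------------------------------------------------------------

MIN_INTER_BLINK_S = 0.5
#: mean-square of a unit-amplitude 300 ms Hann blink train at 12/min —
#: noise fallback scale for traces generated without any blink
_TYPICAL_BLINK_POWER = 0.0225


def _draw_blink_times(spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    """Poisson blink times, thinned to the 500 ms refractory, redrawn
    (up to 100 attempts) until at least one event exists when the
    requested rate is positive."""
    if spec.blink_rate_per_min is None:
        raise InvalidParameterError("blink_rate_per_min is required")
    lo = spec.edge_margin_s
    hi = spec.duration_s - spec.edge_margin_s
    rates = np.atleast_1d(np.asarray(spec.blink_rate_per_min, dtype=float))
    env_rate = float(rates.max())
    if env_rate == 0:
        return np.array([])
    if float(rates.mean()) * spec.duration_s / 60.0 < 1:
        warnings.warn("expected blink count below 1 for this duration", RuntimeWarning,
                      stacklevel=3)
    times: list[float] = []
    for _ in range(100):
        n_cand = rng.poisson(env_rate * spec.duration_s / 60.0)
        cand = np.sort(rng.uniform(lo, hi, n_cand))
        times = []
        for c in cand:
            # honour a per-minute rate profile by thinning against the envelope
            local = spec.rate_for_minute(int(c // 60))
            if local < env_rate and rng.uniform() > local / env_rate:
                continue
            if not times or c - times[-1] >= MIN_INTER_BLINK_S:
                times.append(float(c))
        if times:
            break
    return np.asarray(times)


def gen_eog(spec: SimSpec, times: np.ndarray | None = None) -> tuple[SampledSignal, np.ndarray]:
    """Synthetic vertical-EOG trace and its true blink times.

    Blinks are positive 300 ms Hann deflections (amplitude 1 ± the
    configured jitter) on white background noise.  ``times`` injects a
    known blink-time truth (for paired video/laboratory experiments);
    otherwise times are drawn from the thinned Poisson process.
    Returned truth times mark the deflection centres.
    """
    rng = _rng(spec)
    if times is None:
        times = _draw_blink_times(spec, rng)
    times = np.asarray(times, dtype=float)
    n = int(round(spec.duration_s * spec.fs))
    x = np.zeros(n)
    m = int(round(0.3 * spec.fs))
    bump = np.hanning(m)
    for bt in times:
        i0 = int(round(bt * spec.fs))
        amp = rng.uniform(1 - spec.blink_amplitude_jitter, 1 + spec.blink_amplitude_jitter)
        seg = bump[: max(0, min(m, n - i0))]
        x[i0 : i0 + seg.size] += amp * seg
    if spec.snr_db is not None:
        sigma = _noise_sigma(x, spec.snr_db, fallback_power=_TYPICAL_BLINK_POWER)
        x = x + sigma * rng.standard_normal(n)
    return SampledSignal(x, spec.fs, label="synthetic EOG"), times + 0.15


def gen_eyelid_trace(
    spec: SimSpec, times: np.ndarray | None = None
) -> tuple[EyelidTrace, np.ndarray]:
    """Synthetic 30 fps eyelid-distance trace and its true blink times.

    A constant open-eye aperture carries downward Hann-shaped closure
    transients (150–300 ms) at the truth times, plus the drift+jitter
    noise model described in the module docstring.  Truth times mark
    the closure centres.
    """
    rng = _rng(spec)
    if times is None:
        times = _draw_blink_times(spec, rng)
    times = np.asarray(times, dtype=float)
    n = int(round(spec.duration_s * spec.fs))
    closures = np.zeros(n)
    centers = []
    lo_d, hi_d = spec.blink_duration_range_s
    for bt in times:
        dur = rng.uniform(lo_d, hi_d)
        m = max(2, int(round(dur * spec.fs)))
        i0 = int(round(bt * spec.fs))
        depth = spec.eyelid_blink_depth_px * rng.uniform(
            1 - spec.blink_amplitude_jitter, 1 + spec.blink_amplitude_jitter
        )
        seg = np.hanning(m)[: max(0, min(m, n - i0))]
        closures[i0 : i0 + seg.size] -= depth * seg
        centers.append(bt + dur / 2)
    x = spec.eyelid_baseline_px + closures
    if spec.snr_db is not None:
        sigma = _noise_sigma(
            closures, spec.snr_db,
            fallback_power=_TYPICAL_BLINK_POWER * spec.eyelid_blink_depth_px**2,
        )
        drift = _sps.lfilter([1.0], [1.0, -0.99], rng.standard_normal(n))
        drift = drift / max(np.std(drift), 1e-30)
        x = x + sigma * (np.sqrt(0.8) * drift + np.sqrt(0.2) * rng.standard_normal(n))
    distances = SampledSignal(np.maximum(x, 0.0), spec.fs, label="synthetic eyelid distance")
    trace = EyelidTrace(
        distances=distances,
        left=distances.values.copy(),
        right=distances.values.copy(),
        interpolated=np.zeros(n, dtype=bool),
    )
    return trace, np.asarray(centers)


# ---------------------------------------------------------------------------
# cheek-ROI traces
# ---------------------------------------------------------------------------

PULSE_DETECTION_BAND_BPM = (36.0, 132.0)


def gen_roi_trace(spec: SimSpec) -> tuple[RoiTrace, np.ndarray]:
    """Synthetic cheek-ROI RGB traces and the per-minute true HR.

    The red channel carries the cardiac oscillation (fundamental plus a
    second harmonic at 30% amplitude) common to both cheeks; all
    channels share the common illumination drift; each cheek adds
    independent white noise.  Returns the per-minute ``hr_bpm`` truth.
    """
    if spec.hr_bpm is None:
        raise InvalidParameterError("gen_roi_trace requires hr_bpm")
    hr = np.atleast_1d(np.asarray(spec.hr_bpm, dtype=float))
    if np.any(hr < PULSE_DETECTION_BAND_BPM[0]) or np.any(hr > PULSE_DETECTION_BAND_BPM[1]):
        warnings.warn(
            f"hr_bpm outside the {PULSE_DETECTION_BAND_BPM} bpm detection band",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = _rng(spec)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    minute = np.minimum((t // 60).astype(int), hr.size - 1)
    f_inst = hr[minute] / 60.0
    phase = 2 * np.pi * np.cumsum(f_inst) / spec.fs
    phi = rng.uniform(0, 2 * np.pi)
    pulse = spec.roi_pulse_amplitude * (np.sin(phase + phi) + 0.3 * np.sin(2 * (phase + phi)))
    drift = np.zeros(n)
    if spec.drift_amplitude_ratio > 0:
        for _ in range(3):
            fd = rng.uniform(0.02, 0.1)
            drift += np.sin(2 * np.pi * fd * t + rng.uniform(0, 2 * np.pi))
        drift *= spec.drift_amplitude_ratio * spec.roi_pulse_amplitude / max(
            np.max(np.abs(drift)), 1e-30
        )
    sigma = 0.0
    if spec.snr_db is not None:
        sigma = _noise_sigma(pulse, spec.snr_db, fallback_power=spec.roi_pulse_amplitude**2 / 2)

    def channel(with_pulse: bool) -> np.ndarray:
        base = spec.roi_base_level + drift
        if with_pulse:
            base = base + pulse
        return base + sigma * rng.standard_normal(n)

    trace = RoiTrace(
        r_left=channel(True),
        g_left=channel(False),
        b_left=channel(False),
        r_right=channel(True),
        g_right=channel(False),
        b_right=channel(False),
        fps=spec.fs,
    )
    n_min = max(1, int(np.ceil(spec.duration_s / 60.0 - 1e-9)))
    truth = np.array([hr[min(m, hr.size - 1)] for m in range(n_min)])
    return trace, truth
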