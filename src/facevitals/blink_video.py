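"""Video-based eye-blink rate from 68-point facial landmarks.

Per frame, the eyelid aperture is the distance between the superior and
inferior eyelids, computed from the standard 68-point face annotation:
each eye is a hexagon of six landmarks —

* right eye: 36 (outer corner), 37, 38 (upper lid), 39 (inner corner),
  40, 41 (lower lid);
* left eye: 42 (inner corner), 43, 44 (upper lid), 45 (outer corner),
  46, 47 (lower lid) —

so the aperture per eye is the mean of the two vertical lid pairs
(37–41, 38–40 and 43–47, 44–46) and the trace is the mean over both
eyes.  Frames where the landmark provider failed are linearly
interpolated and flagged.

The 30 fps aperture trace is band-passed 1–3 Hz for noise removal (a
1st-order Butterworth: higher orders ring long enough to double-count
blinks), the detection threshold is the quadratic mean (RMS) of the
filtered trace over the experimental condition, and each excursion of
the filtered trace beyond that threshold counts as one blink.  The
oscillatory lobes a band-pass filter spreads one closure into are
re-united through the Hilbert envelope (which bridges the zero
crossings within a closure), and ring lobes are told apart from a
genuinely distinct neighbouring closure by their relative amplitude
and spacing — see :func:`detect_blinks_video`.  EBR is blinks per
minute, shared with the EOG pipeline
(:func:`facevitals.blink_eog.compute_ebr`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sps

from .blink_eog import BlinkEvent, BlinkEventSet, compute_ebr  # noqa: F401  (shared op)
from .core_signals import (
    BandpassSpec,
    InvalidParameterError,
    SampledSignal,
    bandpass,
    interpolate_gaps,
)

__all__ = [
    "EYE_BAND",
    "LandmarkFrame",
    "EyelidTrace",
    "eyelid_distance",
    "rms_threshold",
    "detect_blinks_video",
    "compute_ebr",
]

#: Band-pass applied to the eyelid-distance trace before thresholding.
EYE_BAND = BandpassSpec(low_hz=1.0, high_hz=3.0, order=1, family="butterworth")

#: (upper, lower) lid landmark index pairs per eye in the 68-point scheme.
RIGHT_EYE_LID_PAIRS = ((37, 41), (38, 40))
LEFT_EYE_LID_PAIRS = ((43, 47), (44, 46))

#: minimum separation between two accepted closures within one envelope
#: excursion (just below the physiological minimum inter-blink interval)
MIN_EVENT_SEPARATION_S = 0.4
#: a candidate weaker than this fraction of its group's strongest event
#: is a filter ring lobe, not a closure of its own
RELATIVE_AMPLITUDE_FLOOR = 0.35
TRANSIENT_GUARD_S = 0.5
DEFAULT_FRAME_SIZE = (640, 480)


@dataclass
class LandmarkFrame:
    """One video frame's 68 landmark coordinates (pixels)."""

    frame_index: int
    points: np.ndarray
    valid: bool = True
    frame_size: tuple[int, int] = DEFAULT_FRAME_SIZE

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.valid:
            if self.points.shape != (68, 2):
                raise InvalidParameterError(
                    f"a valid frame needs 68 (x, y) points, got shape {self.points.shape}"
                )
            w, h = self.frame_size
            if (
                np.any(self.points < 0)
                or np.any(self.points[:, 0] > w)
                or np.any(self.points[:, 1] > h)
            ):
                raise InvalidParameterError("landmark coordinates outside frame bounds")


@dataclass
class EyelidTrace:
    """Per-frame eyelid aperture with per-eye components kept for audit."""

    distances: SampledSignal
    left: np.ndarray
    right: np.ndarray
    interpolated: np.ndarray  # True where the frame was invalid

    @property
    def fps(self) -> float:
        return self.distances.fs


def _eye_distance(points: np.ndarray, pairs) -> float:
    return float(
        np.mean([np.linalg.norm(points[u] - points[l]) for u, l in pairs])
    )


def eyelid_distance(frames, fps: float = 30.0) -> EyelidTrace:
    """Per-frame eyelid aperture from ordered landmark frames.

    Invalid frames are linearly interpolated from their neighbours and
    flagged in ``interpolated``.
    """
    frames = list(frames)
    if not frames:
        raise InvalidParameterError("no frames")
    valid = np.array([f.valid for f in frames], dtype=bool)
    if not valid.any():
        raise InvalidParameterError("no valid frames")
    n = len(frames)
    left = np.zeros(n)
    right = np.zeros(n)
    for i, f in enumerate(frames):
        if f.valid:
            right[i] = _eye_distance(f.points, RIGHT_EYE_LID_PAIRS)
            left[i] = _eye_distance(f.points, LEFT_EYE_LID_PAIRS)
    left = interpolate_gaps(left, valid)
    right = interpolate_gaps(right, valid)
    both = (left + right) / 2.0
    return EyelidTrace(
        distances=SampledSignal(both, fps, label="eyelid distance (px)"),
        left=left,
        right=right,
        interpolated=~valid,
    )


def rms_threshold(
    filtered: SampledSignal, transient_guard_s: float = TRANSIENT_GUARD_S
) -> float:
    """Quadratic mean of the band-passed trace over the condition.

    Filter-transient edge samples are excluded so start-up artefacts do
    not inflate the threshold.
    """
    guard = int(round(transient_guard_s * filtered.fs))
    core = filtered.values[guard : len(filtered.values) - guard or None]
    if core.size == 0:
        core = filtered.values
    if core.size == 0:
        raise InvalidParameterError("empty signal")
    return float(np.sqrt(np.mean(core**2)))


def detect_blinks_video(
    filtered: SampledSignal,
    threshold: float,
    min_event_separation_s: float = MIN_EVENT_SEPARATION_S,
    relative_amplitude_floor: float = RELATIVE_AMPLITUDE_FLOOR,
    transient_guard_s: float = TRANSIENT_GUARD_S,
) -> BlinkEventSet:
    """Blink events from the band-passed eyelid trace.

    Candidate events are the local maxima of the rectified trace above
    the threshold.  Candidates are grouped by contiguous excursions of
    the Hilbert envelope above the threshold — the envelope bridges the
    oscillatory lobes a band-pass filter spreads one closure into, so
    one closure forms one group even though |y| crosses zero inside it.
    Within a group, events are accepted greedily by amplitude subject to
    a ``min_event_separation_s`` gap and a ``relative_amplitude_floor``
    relative to the group's strongest event: filter ring lobes are both
    nearby and several times weaker than their parent closure, whereas a
    genuinely distinct closure is comparably deep and at least the
    physiological inter-blink interval away.  A sustained
    supra-threshold plateau has a single flat rectified maximum, so it
    counts once regardless of duration.  Events inside the
    filter-transient edge regions are discarded.
    """
    if threshold < 0:
        raise InvalidParameterError("threshold must be non-negative")
    y = filtered.values
    fs = filtered.fs
    env = np.abs(_sps.hilbert(y))
    ay = np.abs(y)
    guard = int(round(transient_guard_s * fs))
    sep = max(1, int(round(min_event_separation_s * fs)))
    cand, _ = _sps.find_peaks(ay, height=threshold)
    above = env > threshold
    run_id = np.cumsum(np.r_[above[:1].astype(int),
                             (np.diff(above.astype(int)) == 1).astype(int)])
    cand = cand[above[cand]] if cand.size else cand
    peaks_list: list[int] = []
    for rid in (np.unique(run_id[cand]) if cand.size else []):
        group = sorted((int(p) for p in cand if run_id[p] == rid),
                       key=lambda p: -ay[p])
        accepted = [group[0]]
        for p in group[1:]:
            if ay[p] < relative_amplitude_floor * ay[accepted[0]]:
                break
            if all(abs(p - q) >= sep for q in accepted):
                accepted.append(p)
        peaks_list.extend(accepted)
    peaks = np.asarray(sorted(peaks_list), dtype=int)
    if peaks.size:
        peaks = peaks[(peaks >= guard) & (peaks < len(y) - guard)]
    events = [
        BlinkEvent(t_peak_s=p / fs, amplitude=float(y[p]), correlation=float("nan"))
        for p in peaks
    ]
    return BlinkEventSet(events=events, condition_duration_s=filtered.duration_s)


def blinks_from_trace(trace: EyelidTrace) -> BlinkEventSet:
    """Full pipeline: band-pass → RMS threshold → thresholded events."""
    filtered = bandpass(trace.distances, EYE_BAND)
    thr = rms_threshold(filtered)
    return detect_blinks_video(filtered, thr)
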