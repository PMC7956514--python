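# facevitals

Contactless estimation of heart rate and eye-blink rate from facial
video — alongside the laboratory reference pipelines (ECG, EOG) and the
agreement statistics needed to validate one against the other.

Ordinary webcam footage carries two neurophysiological signals.  Blood
volume pulsations subtly modulate skin colour, so the spatial mean of
the red channel over the cheeks oscillates at the cardiac frequency
(remote photoplethysmography, rPPG); and the distance between the upper
and lower eyelid landmarks collapses transiently at every blink.
`facevitals` turns these traces into per-minute heart rate (HR, bpm)
and per-condition eye-blink rate (EBR, blinks/min), implements the
matching laboratory pipelines — R-peak detection on single-lead ECG and
template-matched blink detection on vertical EOG — and provides the
statistics layer used to compare the two modalities.  It is written for
researchers in human-factors, affective-computing and physiological
monitoring who need a tested, fully reproducible reference chain rather
than a black box.

## The core methods

**HR from video.**  Red-channel cheek-ROI traces at 30 fps are cleaned
by PCA (the retained component maximises the 0.6–2.2 Hz in-band power
ratio after detrending), detrended with the smoothness-priors method —
the trend solves (I + λ²D₂ᵀD₂)τ = x with D₂ the second-difference
operator, λ set from a 0.060 Hz high-pass cutoff — band-passed with a
128-tap Hamming FIR (0.6–2.2 Hz), z-scored, and scanned by a 100-frame
sliding window whose zero-padded FFT peak (parabolically interpolated)
gives one HR estimate per second; each minute reports the median.

**EBR from video.**  Per-frame eyelid apertures from the standard
68-point landmarks are band-passed 1–3 Hz; the threshold is the
quadratic mean (RMS) of the filtered trace over the condition, and each
excursion beyond it is one blink.

**Laboratory references.**  ECG: 1–4 Hz Butterworth, point-wise cube,
adaptive peak picking, HR = 60/mean(RR) per 60 s window.  EOG: 2–10 Hz
Butterworth, threshold = mean(eyes-open) + 3·robustStdDev, Pearson
correlation > 0.9 against a 300 ms blink template.

**Statistics.**  Baseline subtraction per subject; Shapiro–Wilk-gated
paired testing (paired t or Wilcoxon signed-rank, computed in-repo);
repeated-measures correlation r = sign(b)·√(SSm/(SSm+SSe)) with
dof = N − k − 1; percentage differences against the laboratory device.

A synthetic-data module generates every input with known ground truth
(ECG with stereotyped PQRST beats, EOG and eyelid traces with Hann
blink deflections, cheek-ROI traces with pulse, harmonics, illumination
drift and noise), so the whole validation runs without any recordings.

## Worked example

```python
import numpy as np
from facevitals import SimSpec, gen_roi_trace, gen_ecg, hr_from_roi, hr_from_ecg
from facevitals import gen_eyelid_trace, blinks_from_trace, compute_ebr

truth_bpm = [72, 76, 80]   # per-minute heart rate, 3 minutes
roi, _ = gen_roi_trace(SimSpec(duration_s=180, fs=30, seed=7, hr_bpm=truth_bpm,
                               snr_db=5, drift_amplitude_ratio=3.0))
video_hr = hr_from_roi(roi)
ecg, _ = gen_ecg(SimSpec(duration_s=180, fs=256, seed=7, hr_bpm=truth_bpm, snr_db=10))
lab_hr = hr_from_ecg(ecg)
print("minute  truth  video-HR  ECG-HR")
for m in range(3):
    print(f"{m:>6}  {truth_bpm[m]:>5}  {video_hr.bpm[m]:8.1f}  {lab_hr.bpm[m]:6.1f}")

lid, blink_times = gen_eyelid_trace(SimSpec(duration_s=120, fs=30, seed=7,
                                            blink_rate_per_min=15, snr_db=10))
events = blinks_from_trace(lid)
print(f"\nblinks: {len(blink_times)} generated, {len(events)} detected "
      f"-> EBR {compute_ebr(events):.1f} /min")
```

prints

```
minute  truth  video-HR  ECG-HR
     0     72      71.9    72.0
     1     76      76.0    76.0
     2     80      79.9    80.0

blinks: 29 generated, 29 detected -> EBR 14.5 /min
```

The video pipeline recovers each minute's true rate to within a
fraction of a bpm despite an illumination drift three times the pulse
amplitude and 5 dB of sensor noise, matching the ECG reference; the
blink pipeline recovers the exact event count, giving the 14.5
blinks/min EBR for the 2-minute condition.

The same pipelines are available from the shell:

```
facevitals simulate roi --duration 120 --hr 66 --out-prefix run1
facevitals hr-video --roi-trace run1_roi.csv --out run1_hr.csv
```

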