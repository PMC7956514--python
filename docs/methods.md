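# Methods

`facevitals` implements two contactless vital-sign estimators — heart
rate (HR) from remote photoplethysmography (rPPG) on facial video, and
eye-blink rate (EBR) from facial-landmark eyelid apertures — together
with the laboratory reference pipelines they are validated against
(single-lead ECG, vertical EOG) and the agreement statistics that
quantify how well the contactless and laboratory estimates match.
All pipelines operate offline on uniformly sampled traces: 256 Hz
biosignals and 30 fps video-derived signals.

## Signal model and pipelines

### Heart rate from cheek-ROI video (rPPG)

Blood-volume pulsations modulate skin reflectance; the spatial mean of
the red channel over two cheek rectangles (placed below the eyes,
medial edge at the nose-tip column, sized by the inter-ocular
distance) carries a cardiac-band oscillation of order 1 digital level
on top of illumination drift that can be several times larger.
The chain is: PCA → detrend → band-pass → z-score → windowed
spectral peak.

1. **PCA.** The left/right red sub-traces are standardised and
   decomposed by principal-component analysis.  The retained component
   maximises the in-band (0.6–2.2 Hz) to out-of-band power ratio *of
   its detrended spectrum*, sign-fixed to correlate positively with the
   mean red trace.  Ranking raw spectra instead would let a strong
   common drift component dominate the ratio of every pulse-carrying
   component and select the noise-difference component — a measured
   end-to-end failure mode.
2. **Smoothness-priors detrending.**  The trend is
   `τ = (I + λ² D₂ᵀD₂)⁻¹ x`, where `D₂` is the second-difference
   operator — a regularised least-squares fit penalising trend
   curvature — and the output is `x − τ`.  The operator acts as a
   high-pass whose half-power corner `f_c` satisfies
   `λ = 1 / (4 sin²(π f_c / fs))`.  The default derives λ from
   `f_c = 0.060 Hz` at the working rate (λ ≈ 6333 at 30 fps).  An
   explicitly supplied λ is honoured instead.  Rationale: a fixed small
   λ applied directly at 30 fps would place the corner near 1.5 Hz,
   attenuating a 1.2 Hz pulse to 8% of its power and making every HR
   below ~66 bpm lock onto its second harmonic; deriving λ from the
   cutoff removes illumination drift (≤ 0.1 Hz) while leaving the
   cardiac band untouched.  The system is pentadiagonal symmetric
   positive-definite and solved by banded Cholesky in O(N); the unit
   tests pin it against an independent dense solve.
3. **Band-pass.**  128-tap Hamming windowed-sinc FIR, 0.6–2.2 Hz
   (36–132 bpm).  Linear-phase FIRs are applied as a single
   delay-compensated convolution — exactly zero phase for symmetric
   taps, and the designed magnitude response applies unsquared (a
   forward–backward pass would square it, halving the effective
   passband).  The taps are shifted to a zero DC sum so constants map
   exactly to zero.  The first/last ⌈(taps−1)/2⌉ samples are start-up
   transients and are excluded from analysis windows.
4. **z-score.**  `(x − μ)/σ` with the population SD; a constant input
   returns zeros with a degeneracy flag.
5. **Spectral HR.**  100-frame sliding windows (3.33 s at 30 fps)
   advance by 1 s.  Each window is Hann-tapered, zero-padded to 1024
   points, and HR = 60 × the in-band power-spectrum argmax refined by
   three-point parabolic interpolation.  The raw 100-frame resolution
   is 0.3 Hz ≡ 18 bpm, so padding plus interpolation is what makes the
   window usable.  A window is invalid when its in-band peak sits on a
   band edge or fails a 5× prominence floor over the median in-band
   power.  The per-minute HR is the median of the valid window
   estimates in that minute (robust to occasional harmonic or noise
   picks); a minute with under 50% valid windows is flagged invalid.

### Heart rate from ECG (laboratory reference)

5th-order Butterworth band-pass 1–4 Hz (zero-phase, second-order
sections), point-wise cube to emphasise R peaks over artefacts
(sign-preserving; lead polarity is auto-detected from the skewness of
the cubed trace and flipped when negative), peak picking above an
adaptive threshold — 0.4 × a rolling 95th percentile over 10 s windows
evaluated every 2.5 s and interpolated, which is scale-free and tracks
amplitude drift — with a 0.3 s minimum inter-peak interval (200 bpm
cap).  HR per non-overlapping 60 s window is 60 / mean(RR) over the
intervals starting in the window; windows with fewer than two peaks,
or outside 30–200 bpm, are flagged invalid.

### Eye-blink rate from EOG (laboratory reference)

The Fpz-channel estimate of the vertical EOG is band-passed 2–10 Hz
(5th-order Butterworth, zero-phase).  The detection threshold comes
from an eyes-open calibration segment:

    threshold = mean(segment) + 3 × robust_std_dev(segment)

with the robust spread implemented literally as the mean absolute
deviation (a `scaled_mad` estimator — 1.4826 × MAD — is available as an
option).  A real eyes-open baseline contains blinks, and the formula
relies on that: with a blink-free segment the threshold collapses onto
the in-band noise floor and smooth noise bumps start passing the
correlation gate.  Candidate peaks above the threshold are matched
against a 300 ms unit-peak Hann template by Pearson correlation,
centred on the local maximum; candidates with r > 0.9 are blinks.  A
filtered blink still correlates > 0.99 with the raw Hann bump, so the
template needs no band matching.  Acceptance is greedy by amplitude
with a 0.4 s minimum separation, and a candidate smaller than half of
an already-accepted peak within 2 s is discarded as a ring echo of
that blink: zero-phase 10th-order-effective filtering spreads each
blink into echoes at 0.3–1.4 s that would otherwise pass the
correlation gate.  A data-driven template (mean of supra-threshold
calibration excursions) is available.  EBR = blinks per minute.

### Eye-blink rate from video landmarks

Per frame, the eyelid aperture per eye is the mean distance of the two
upper↔lower lid landmark pairs of the standard 68-point annotation
(right eye 37–41 and 38–40; left eye 43–47 and 44–46), averaged over
both eyes; frames where the landmark provider failed are linearly
interpolated and flagged.  The landmark provider itself is a pluggable
interface (any callable producing a 68-point frame); no detector is
bundled or required.

The aperture trace is band-passed 1–3 Hz with a **1st-order**
Butterworth (orders ≥ 2 ring long enough to double-count blinks —
measured), the threshold is the quadratic mean (RMS) of the filtered
trace over the condition (filter-transient edges excluded), and events
are excursions beyond the threshold.  Because a band-pass filter
spreads one closure into several oscillatory lobes, candidates (local
maxima of |y| above threshold) are grouped by contiguous excursions of
the Hilbert envelope — which bridges the zero crossings within one
closure — and within a group accepted greedily by amplitude with a
0.4 s minimum separation and a 0.35 relative-amplitude floor: ring
lobes are nearby and several times weaker than their parent closure,
while a genuinely distinct closure is comparably deep and at least the
physiological inter-blink interval away.  A sustained supra-threshold
plateau counts once.

### Agreement statistics

Condition values are baseline-normalised (each subject's resting
baseline subtracted) before testing.  Paired comparisons are gated by
Shapiro–Wilk on the paired differences at α = 0.05 — the differences
are the quantity the paired t-test assumes normal; gating on both
samples is available — choosing the paired t-test when normality is
not rejected and the Wilcoxon signed-rank test otherwise.  The
Wilcoxon statistic is computed in-repo: exact null distribution by
dynamic programming for n ≤ 25 without ties, tie-corrected normal
approximation with continuity correction otherwise (cross-checked
against an independent implementation in the tests).  The
repeated-measures correlation (rmcorr) is the common within-subject
association: ANCOVA with subject intercepts and a shared slope, where
`r` equals the Pearson correlation of within-subject-centred data
signed by the common slope, `dof = N_obs − N_subjects − 1`, and `p`
from `t = r·sqrt(dof/(1−r²))`.  Percentage difference is the mean over
subjects of `|video − lab| / |lab| × 100`, the laboratory device being
the reference.  No multiplicity correction is applied; each
task/metric combination is tested separately at α = 0.05.

## Synthetic data

The generators in `facevitals.synthetic_data` emulate every input the
pipelines consume and return the ground truth alongside, so all tests
are self-scoring and no external data are needed.

* **ECG** — stereotyped PQRST complexes (Gaussian bumps, upright unit
  R spike) at the per-minute true rate, optional fractional RR jitter,
  additive white noise.
* **EOG** — positive 300 ms Hann deflections (amplitude 1 ± 20%
  jitter) on white background noise, blink times from a Poisson
  process thinned to a 500 ms minimum inter-blink interval.
* **Eyelid trace** — a 6 px open aperture with 150–300 ms downward
  Hann closures of ~5 px; noise is 80% (power) slow drift (AR(1),
  coefficient 0.99 — head and gaze motion) plus 20% white per-frame
  landmark jitter.
* **Cheek ROI** — red channel carries the pulse (fundamental plus a
  second harmonic at 30% amplitude, so spectral peak pickers are
  exercised against harmonic confusion) common to both cheeks; all
  channels share a common low-frequency illumination drift (three
  random sinusoids in 0.02–0.1 Hz, amplitude set as a multiple of the
  pulse amplitude); each cheek adds independent white noise.

`snr_db` is uniformly the power ratio of the signal component (blink
deflections, QRS train, pulse oscillation) to the noise.  Blink-time
draws are conditioned on at least one event per trace: an awake
subject at the supported rates always blinks within a minute, and a
zero-event trace makes any RMS-derived threshold degenerate.

What the generators deliberately do **not** model: head motion and
non-rigid facial deformation, specular reflections, skin-tone
variation, landmark-tracking failures correlated with blinks,
arrhythmic RR structure, saccadic EOG activity, or rendered video
frames (trace-level only).  Passing the recovery experiments therefore
shows the algorithmic chain is correct and robust to the modelled
noise, drift and harmonics — not that field performance on arbitrary
webcam footage is guaranteed.

## Validation experiments

`facevitals.validation` (driven by `scripts/acceptance.py` and
`tests/test_acceptance.py`) re-runs, from freshly generated truth:

* rPPG HR recovery at 48–108 bpm with 5× drift and 0 dB SNR (20 seeds
  per level, 120 s traces): per-minute MAE ≤ 3 bpm.
* ECG HR recovery at 40–120 bpm and 10 dB (20 seeds, 70 s): every 60 s
  window within 1 bpm.
* Video blink counting at 5–30 blinks/min (50 seeds per rate, 120 s):
  exact counts at 10 dB, within ±1 blink/min at 5 dB.
* EOG blink detection (100 runs, 15 dB, calibration-derived
  threshold): sensitivity ≥ 0.95 with zero false positives.
* Numerical oracles: the banded detrending solve against a dense
  matrix solve (≤ 1e-8 for N up to 2000 at λ = 10; at λ ≈ 6333 the
  system's condition number ≈ 6·10⁸ puts 1e-8 beyond float64, and the
  unit tests use 1e-6 there), and rmcorr against a brute-force ANCOVA
  normal-equations solve (≤ 1e-10 over 50 random designs, exact ±1 on
  perfect common-slope data).
* Filter contracts: designed responses within [0.9, 1.1] in the
  passband and below −20 dB at the stop-band probes.
* A paired 15-subject study: the same per-minute HR truth and the same
  blink times drive both the laboratory (ECG/EOG) and video
  (ROI/eyelid) recordings over a baseline plus two conditions, the
  non-nominal condition raising true HR by 8 bpm and EBR by
  8 blinks/min.  The statistics layer must show device agreement
  (paired p > 0.05, per-minute rmcorr r ≥ 0.6) and condition
  discrimination (p < 0.05) for both metrics.

Problem sizes are the package's own choice to keep the full set at a
few minutes on one CPU; every experiment accepts its sizes as
arguments.

## Numerical and design notes

* All Butterworth filtering is offline zero-phase over second-order
  sections; signals shorter than the stable-padding requirement raise
  a dedicated error rather than being truncated silently.
* The one-sided FFT power spectrum is normalised so that
  `sum(power) = sum(x²)` exactly (discrete Parseval; DC and Nyquist
  bins counted once).
* Parabolic peak interpolation uses the three power bins around the
  argmax; ties in the quadratic fit fall back to the bin centre.
* `hr_from_peaks` assigns each RR interval to the window containing
  its starting peak; the trailing partial window is reported with its
  actual duration.
* Degenerate inputs carry flags rather than exceptions where the
  degenerate outcome is meaningful: constant traces z-score to zeros
  (`degenerate`), a flat ECG yields an empty peak train (`no_peaks`),
  a single red sub-trace skips PCA (`pca_fallback`).
* CSV I/O is comma-separated UTF-8 with a mandatory header; parse
  errors name the offending row, and a `time` column with > 1% jitter
  of the sampling interval is rejected rather than resampled.

## Known limitations

* No motion compensation, skin segmentation, or chrominance-model
  rPPG variants (CHROM/POS); the red channel with PCA over two cheek
  ROIs is the only extraction path.
* The blink pipelines assume monophasic closures; saccades, half
  blinks and eye-rubbing artefacts are out of scope.
* The rPPG band (0.6–2.2 Hz) hard-limits detectable HR to 36–132 bpm.
* Real-time/streaming operation is out of scope; all filters are
  acausal.
* The 68-point landmark detector itself is not part of the package —
  any provider can be plugged in, and detector quality directly
  bounds eyelid-trace quality.
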