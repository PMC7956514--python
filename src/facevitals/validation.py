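"""Self-contained validation experiments.

Each function runs one recovery or oracle experiment end-to-end on
synthetic ground truth and returns summary numbers.  They are used by
the acceptance test suite and by ``scripts/acceptance.py``; problem
sizes (trace durations, seed counts) are chosen so the full set runs in
a few minutes on one CPU.

The paired video/laboratory experiment (:func:`method_agreement_study`)
mirrors a 15-participant validation study: for every virtual subject
the same physiological truth (per-minute heart rate, blink times)
drives both the laboratory recordings (ECG, EOG) and the video-derived
recordings (cheek-ROI traces, eyelid distances); the statistics layer
then quantifies method agreement (paired tests, repeated-measures
correlation, percentage differences) and condition discrimination
(nominal vs. non-nominal).
"""

from __future__ import annotations

import numpy as np

from .blink_eog import (
    compute_blink_threshold,
    detect_blinks_eog,
    make_blink_template,
)
from .blink_video import blinks_from_trace
from .core_signals import BandpassSpec, SampledSignal, bandpass, design_fir_taps
from .hr_ecg import hr_from_ecg
from .hr_video import DetrendSpec, detrend_smoothness_priors, hr_from_roi
from .stats_compare import paired_compare, percent_difference, rmcorr
from .synthetic_data import SimSpec, _draw_blink_times, gen_ecg, gen_eog, gen_eyelid_trace, gen_roi_trace

EOG_BAND = BandpassSpec(2.0, 10.0, 5)


# ---------------------------------------------------------------------------
# recovery experiments
# ---------------------------------------------------------------------------


def hr_video_recovery(
    hr_levels=(48, 60, 72, 90, 108),
    seeds_per_level: int = 20,
    snr_db: float = 0.0,
    drift_ratio: float = 5.0,
    duration_s: float = 120.0,
    base_seed: int = 0,
) -> dict:
    """Per-minute HR error of the rPPG pipeline on synthetic ROI traces."""
    errors = []
    per_level = {}
    for bpm in hr_levels:
        level_err = []
        for k in range(seeds_per_level):
            spec = SimSpec(duration_s=duration_s, fs=30.0, seed=base_seed + 7919 * k + bpm,
                           hr_bpm=bpm, snr_db=snr_db, drift_amplitude_ratio=drift_ratio)
            roi, truth = gen_roi_trace(spec)
            series = hr_from_roi(roi)
            for m, est in enumerate(series.bpm):
                if series.valid[m]:
                    level_err.append(abs(est - truth[min(m, truth.size - 1)]))
        per_level[bpm] = float(np.mean(level_err))
        errors.extend(level_err)
    return {
        "mae_bpm": float(np.mean(errors)),
        "worst_level_mae_bpm": float(max(per_level.values())),
        "per_level_mae": per_level,
        "n_windows": len(errors),
    }


def hr_ecg_recovery(
    hr_levels=(40, 60, 72, 90, 120),
    seeds_per_level: int = 20,
    snr_db: float = 10.0,
    duration_s: float = 70.0,
    base_seed: int = 0,
) -> dict:
    """Windowed HR error of the ECG pipeline on synthetic recordings."""
    errors = []
    for bpm in hr_levels:
        for k in range(seeds_per_level):
            spec = SimSpec(duration_s=duration_s, fs=256.0, seed=base_seed + 104729 * k + bpm,
                           hr_bpm=bpm, snr_db=snr_db, rr_jitter=0.0)
            ecg, _ = gen_ecg(spec)
            series = hr_from_ecg(ecg)
            errors.extend(abs(series.bpm[series.valid] - bpm))
    return {
        "max_abs_error_bpm": float(np.max(errors)),
        "mae_bpm": float(np.mean(errors)),
        "n_windows": len(errors),
    }


def ebr_video_recovery(
    rates=(5, 10, 15, 20, 30),
    seeds_per_level: int = 50,
    snr_db: float = 10.0,
    duration_s: float = 120.0,
    base_seed: int = 0,
) -> dict:
    """Blink-count recovery of the video pipeline on eyelid traces."""
    count_errors = []
    for rate in rates:
        for k in range(seeds_per_level):
            spec = SimSpec(duration_s=duration_s, fs=30.0, seed=base_seed + 6151 * k + rate,
                           blink_rate_per_min=rate, snr_db=snr_db)
            trace, truth = gen_eyelid_trace(spec)
            count_errors.append(len(blinks_from_trace(trace)) - len(truth))
    count_errors = np.asarray(count_errors)
    rate_errors = np.abs(count_errors) / (duration_s / 60.0)
    return {
        "exact_fraction": float(np.mean(count_errors == 0)),
        "max_abs_rate_error_per_min": float(rate_errors.max()),
        "n_runs": int(count_errors.size),
    }


def ebr_eog_recovery(
    n_runs: int = 100,
    rate_per_min: float = 12.0,
    snr_db: float = 15.0,
    duration_s: float = 60.0,
    base_seed: int = 0,
) -> dict:
    """Sensitivity / false positives of the EOG blink detector.

    The detection threshold follows the calibration formula (mean of the
    band-passed eyes-open segment plus three robust deviations) on a
    separately generated eyes-open recording of the same subject.
    """
    template = make_blink_template(256.0)
    tp = 0
    fn = 0
    fp = 0
    for k in range(n_runs):
        spec = SimSpec(duration_s=duration_s, fs=256.0, seed=base_seed + 13 * k,
                       blink_rate_per_min=rate_per_min, snr_db=snr_db)
        raw, truth = gen_eog(spec)
        calib_raw, _ = gen_eog(
            SimSpec(duration_s=60.0, fs=256.0, seed=base_seed + 13 * k + 50021,
                    blink_rate_per_min=rate_per_min, snr_db=snr_db)
        )
        filtered = bandpass(raw, EOG_BAND)
        threshold = compute_blink_threshold(bandpass(calib_raw, EOG_BAND))
        det = detect_blinks_eog(filtered, threshold, template).peak_times_s
        used = set()
        for t in det:
            d = np.abs(truth - t)
            j = int(np.argmin(d))
            if d[j] < 0.2 and j not in used:
                tp += 1
                used.add(j)
            else:
                fp += 1
        fn += len(truth) - len(used)
    return {
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "false_positives_total": fp,
        "n_runs": n_runs,
    }


# ---------------------------------------------------------------------------
# numerical oracles
# ---------------------------------------------------------------------------


def detrend_oracle_deviation(sizes=(100, 500, 2000), lam: float = 10.0,
                             base_seed: int = 0) -> dict:
    """Banded smoothness-priors solve vs. an independent dense solve."""
    worst = 0.0
    for n in sizes:
        rng = np.random.default_rng(base_seed + n)
        x = rng.standard_normal(n).cumsum()
        d2 = np.zeros((n - 2, n))
        for i in range(n - 2):
            d2[i, i : i + 3] = [1.0, -2.0, 1.0]
        trend = np.linalg.solve(np.eye(n) + lam**2 * (d2.T @ d2), x)
        oracle = x - trend
        out = detrend_smoothness_priors(SampledSignal(x, 30.0), DetrendSpec(lambda_=lam))
        worst = max(worst, float(np.max(np.abs(out.values - oracle))))
    return {"max_abs_deviation": worst, "sizes": list(sizes)}


def rmcorr_oracle_deviation(n_designs: int = 50, base_seed: int = 0) -> dict:
    """rmcorr vs. a brute-force ANCOVA normal-equations solve, plus the
    exact r = +-1 contracts on perfect common-slope data."""
    rng = np.random.default_rng(base_seed)
    worst = 0.0
    for _ in range(n_designs):
        n_subj = int(rng.integers(3, 7))
        n_per = int(rng.integers(3, 8))
        slope = rng.uniform(-3, 3)
        subjects, xs, ys = [], [], []
        for s in range(n_subj):
            x = rng.uniform(0, 10, n_per)
            y = slope * x + rng.uniform(-20, 20) + rng.standard_normal(n_per)
            subjects.extend([s] * n_per)
            xs.extend(x)
            ys.extend(y)
        subjects = np.asarray(subjects)
        x = np.asarray(xs)
        y = np.asarray(ys)
        labels = np.unique(subjects)
        D = np.column_stack([(subjects == s).astype(float) for s in labels] + [x])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        ss_err = float(((y - D @ beta) ** 2).sum())
        D0 = D[:, :-1]
        beta0, *_ = np.linalg.lstsq(D0, y, rcond=None)
        ss_0 = float(((y - D0 @ beta0) ** 2).sum())
        ss_measure = ss_0 - ss_err
        r_oracle = float(np.sign(beta[-1]) * np.sqrt(ss_measure / (ss_measure + ss_err)))
        r = rmcorr(subjects, x, y).r
        worst = max(worst, abs(r - r_oracle))
    # exact contracts
    subjects = np.repeat(np.arange(4), 5)
    x = np.tile(np.arange(5.0), 4)
    up = rmcorr(subjects, x, 2.0 * x + np.repeat(np.arange(4.0) * 10, 5)).r
    down = rmcorr(subjects, x, -1.0 * x + np.repeat(np.arange(4.0) * 10, 5)).r
    return {
        "max_abs_deviation": worst,
        "r_perfect_positive": up,
        "r_perfect_negative": down,
        "n_designs": n_designs,
    }


def filter_contract_gains() -> dict:
    """Designed filter responses at the probe frequencies."""
    from scipy import signal as sps

    fir = BandpassSpec(0.6, 2.2, 128, "hamming_fir")
    taps = design_fir_taps(fir, 30.0)
    w, h = sps.freqz(taps, worN=16384, fs=30.0)

    def gain(freq):
        return float(np.abs(h[np.argmin(np.abs(w - freq))]))

    sos = sps.butter(5, [2, 10], btype="band", fs=256.0, output="sos")
    w2, h2 = sps.sosfreqz(sos, worN=16384, fs=256.0)

    def gain_iir(freq):
        return float(np.abs(h2[np.argmin(np.abs(w2 - freq))]))

    return {
        "fir_passband_gain_1p2hz": gain(1.2),
        "fir_stopband_gain_5hz": gain(5.0),
        "butter_passband_gain_5hz": gain_iir(5.0),
        "butter_stopband_gain_0p5hz": gain_iir(0.5),
    }


# ---------------------------------------------------------------------------
# paired video / laboratory study
# ---------------------------------------------------------------------------


def _minute_counts(times: np.ndarray, n_minutes: int) -> np.ndarray:
    return np.array([np.sum((times >= 60 * m) & (times < 60 * (m + 1)))
                     for m in range(n_minutes)], dtype=float)


def method_agreement_study(
    n_subjects: int = 15,
    minutes_per_condition: int = 3,
    hr_effect_bpm: float = 8.0,
    ebr_effect_per_min: float = 8.0,
    base_seed: int = 0,
) -> dict:
    """Paired synthetic validation study: same truth, two 'devices'.

    Per subject: a 60 s resting baseline and two task conditions
    (nominal, non-nominal) of ``minutes_per_condition`` minutes.  The
    non-nominal condition raises the true heart rate by
    ``hr_effect_bpm`` and the blink rate by ``ebr_effect_per_min``.
    Laboratory recordings are 256 Hz ECG / EOG; video recordings are
    30 fps ROI / eyelid traces generated from the same truth.
    """
    rng = np.random.default_rng(base_seed)
    fs_bio, fps = 256.0, 30.0
    dur = minutes_per_condition * 60.0
    template = make_blink_template(fs_bio)

    hr_lab_min, hr_vid_min = [], []  # per-minute paired HR values
    ebr_lab_min, ebr_vid_min = [], []
    subj_min = []
    cond_rows = []  # (subject, condition, metric, method) -> value

    for s in range(n_subjects):
        hr_base = rng.normal(70, 4)
        ebr_base = float(np.clip(rng.normal(12, 2), 6, 20))
        seed0 = base_seed + 1000 * s

        # eyes-open calibration for the EOG threshold
        calib_raw, _ = gen_eog(SimSpec(duration_s=60, fs=fs_bio, seed=seed0 + 17,
                                       blink_rate_per_min=ebr_base, snr_db=15))
        threshold = compute_blink_threshold(bandpass(calib_raw, EOG_BAND))

        for c, cond in enumerate(("baseline", "nominal", "non_nominal")):
            cond_dur = 60.0 if cond == "baseline" else dur
            n_min = int(cond_dur // 60)
            d_hr = 0.0 if cond != "non_nominal" else hr_effect_bpm
            d_ebr = 0.0 if cond != "non_nominal" else ebr_effect_per_min
            hr_truth = np.clip(hr_base + d_hr + rng.normal(0, 4, n_min), 45, 130)
            ebr_rate = float(np.clip(ebr_base + d_ebr + rng.normal(0, 1.5), 4, 35))

            # ----- heart rate: ECG (lab) and ROI trace (video), same truth
            ecg, _ = gen_ecg(SimSpec(duration_s=cond_dur, fs=fs_bio, seed=seed0 + 31 * c,
                                     hr_bpm=hr_truth, snr_db=10))
            roi, _ = gen_roi_trace(SimSpec(duration_s=cond_dur, fs=fps, seed=seed0 + 31 * c,
                                           hr_bpm=hr_truth, snr_db=5,
                                           drift_amplitude_ratio=2.0))
            lab_hr = hr_from_ecg(ecg)
            vid_hr = hr_from_roi(roi)

            # ----- blinks: one blink-time truth for both devices
            blink_spec = SimSpec(duration_s=cond_dur, fs=fs_bio, seed=seed0 + 77 * c,
                                 blink_rate_per_min=ebr_rate, snr_db=15)
            times = _draw_blink_times(blink_spec, np.random.default_rng(seed0 + 77 * c))
            eog, truth_eog = gen_eog(blink_spec, times=times)
            lid_spec = SimSpec(duration_s=cond_dur, fs=fps, seed=seed0 + 77 * c,
                               blink_rate_per_min=ebr_rate, snr_db=10)
            lid, _ = gen_eyelid_trace(lid_spec, times=times)
            lab_events = detect_blinks_eog(bandpass(eog, EOG_BAND), threshold, template)
            vid_events = blinks_from_trace(lid)
            lab_counts = _minute_counts(lab_events.peak_times_s, n_min)
            vid_counts = _minute_counts(vid_events.peak_times_s, n_min)

            lab_hr_mean = float(np.mean(lab_hr.bpm[lab_hr.valid]))
            vid_hr_mean = float(np.mean(vid_hr.bpm[vid_hr.valid]))
            for method, value in (("laboratory", lab_hr_mean), ("video", vid_hr_mean)):
                cond_rows.append((s, cond, "HR", method, value))
            for method, value in (("laboratory", lab_counts.mean()),
                                  ("video", vid_counts.mean())):
                cond_rows.append((s, cond, "EBR", method, float(value)))

            if cond != "baseline":
                valid = lab_hr.valid & vid_hr.valid
                hr_lab_min.extend(lab_hr.bpm[valid])
                hr_vid_min.extend(vid_hr.bpm[valid])
                ebr_lab_min.extend(lab_counts)
                ebr_vid_min.extend(vid_counts)
                subj_min.extend([s] * int(valid.sum()))

    # ---- per-minute repeated-measures correlation between the devices
    subj_min = np.asarray(subj_min)
    rm_hr = rmcorr(subj_min, np.asarray(hr_lab_min), np.asarray(hr_vid_min))
    # blink minutes align one-to-one with HR minutes by construction
    rm_ebr = rmcorr(subj_min, np.asarray(ebr_lab_min), np.asarray(ebr_vid_min))

    # ---- condition-level statistics on baseline-normalised values
    import pandas as pd

    df = pd.DataFrame(cond_rows, columns=["subject", "condition", "metric", "method", "value"])

    def norm_values(metric, method, cond):
        vals = df[(df.metric == metric) & (df.method == method)]
        piv = vals.pivot_table(index="subject", columns="condition", values="value")
        return (piv[cond] - piv["baseline"]).to_numpy()

    out = {
        "rmcorr_r_hr": rm_hr.r,
        "rmcorr_p_hr": rm_hr.p_value,
        "rmcorr_r_ebr": rm_ebr.r,
        "rmcorr_p_ebr": rm_ebr.p_value,
        "n_minutes": int(subj_min.size),
        "n_subjects": n_subjects,
    }
    for metric in ("HR", "EBR"):
        vid = np.concatenate([norm_values(metric, "video", c) for c in ("nominal", "non_nominal")])
        lab = np.concatenate([norm_values(metric, "laboratory", c)
                              for c in ("nominal", "non_nominal")])
        agree = paired_compare(vid, lab)
        out[f"method_p_{metric.lower()}"] = agree.p_value
        disc = paired_compare(norm_values(metric, "video", "non_nominal"),
                              norm_values(metric, "video", "nominal"))
        out[f"condition_p_{metric.lower()}"] = disc.p_value
        raw = df[(df.metric == metric) & (df.condition != "baseline")]
        piv = raw.pivot_table(index="subject", columns="method", values="value")
        out[f"percent_difference_{metric.lower()}"] = percent_difference(
            piv["video"].to_numpy(), piv["laboratory"].to_numpy())
    return out
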