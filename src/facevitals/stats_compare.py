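"""Device-agreement statistics for the video vs. laboratory comparison.

Measurements are organised as one scalar per
(subject, task, condition, method, metric) cell — e.g. subject 7's mean
heart rate from the video pipeline during the non-nominal condition of
the NB task.  The analysis layer provides:

* **baseline normalisation** — each condition value minus the same
  subject's resting-baseline value, yielding HR′ / EBR′;
* **normality-gated paired testing** — Shapiro–Wilk on the paired
  differences at α = 0.05 decides between the paired Student t-test
  (normality not rejected) and the Wilcoxon signed-rank test; the
  Wilcoxon statistic is computed in-repo, with the exact null
  distribution for n ≤ 25 (no ties) and the tie-corrected normal
  approximation with continuity correction otherwise;
* **repeated-measures correlation (rmcorr)** — the common
  within-subject association between two repeatedly measured variables,
  estimated from the analysis-of-covariance model with subject-specific
  intercepts and a shared slope.  Numerically this equals the Pearson
  correlation of the within-subject-centred data, signed by the common
  slope, with ``dof = N_obs − N_subjects − 1`` and a t-test on
  ``t = r·sqrt(dof / (1 − r²))``;
* **percentage difference** — mean over subjects of
  ``|video − lab| / |lab| × 100`` (laboratory device as reference).

No multiplicity correction is applied: each task/metric combination is
tested separately at α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "ConditionMeasure",
    "PairedTestResult",
    "RmcorrResult",
    "MissingBaselineError",
    "baseline_normalize",
    "normalize_table",
    "wilcoxon_signed_rank",
    "paired_compare",
    "rmcorr",
    "percent_difference",
]

ALPHA = 0.05


class MissingBaselineError(ValueError):
    """A subject/task cell has no baseline measurement to subtract."""


@dataclass(frozen=True)
class ConditionMeasure:
    """One subject × task × condition × method × metric measurement."""

    subject_id: str
    task: str
    condition: str  # nominal | non_nominal | baseline
    method: str  # video | laboratory
    metric: str  # HR | EBR
    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("measurement value must be finite")


@dataclass
class PairedTestResult:
    test_name: str  # t_paired | wilcoxon_signed_rank
    statistic: float
    p_value: float
    n_pairs: int
    normality_p_values: tuple[float, ...]
    degenerate: bool = False


@dataclass
class RmcorrResult:
    r: float
    dof: int
    p_value: float
    n_subjects: int
    n_obs: int


# ---------------------------------------------------------------------------
# baseline normalisation
# ---------------------------------------------------------------------------


def baseline_normalize(value: float, baseline: float) -> float:
    """Condition value minus the subject's resting-baseline value."""
    if not (np.isfinite(value) and np.isfinite(baseline)):
        raise ValueError("value and baseline must be finite")
    return value - baseline


def normalize_table(measures: pd.DataFrame) -> pd.DataFrame:
    """Baseline-subtract a tidy measurement table.

    Expects columns ``subject_id, task, condition, method, metric,
    value``; rows with ``condition == 'baseline'`` supply the per
    (subject, task, method, metric) baseline.  Returns the non-baseline
    rows with an added ``normalized`` column.
    """
    required = {"subject_id", "task", "condition", "method", "metric", "value"}
    missing = required - set(measures.columns)
    if missing:
        raise ValueError(f"measures table missing columns {sorted(missing)}")
    key = ["subject_id", "task", "method", "metric"]
    base = measures[measures["condition"] == "baseline"].set_index(key)["value"]
    if base.index.has_duplicates:
        raise ValueError("duplicate baseline rows for a subject/task/method/metric cell")
    rows = measures[measures["condition"] != "baseline"].copy()
    idx = pd.MultiIndex.from_frame(rows[key])
    missing_idx = ~idx.isin(base.index)
    if missing_idx.any():
        cell = rows[missing_idx].iloc[0]
        raise MissingBaselineError(
            f"no baseline for subject {cell['subject_id']!r}, task {cell['task']!r}, "
            f"method {cell['method']!r}, metric {cell['metric']!r}"
        )
    rows["normalized"] = rows["value"].to_numpy() - base.loc[idx].to_numpy()
    return rows


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (in-repo)
# ---------------------------------------------------------------------------


def _exact_wplus_sf_cdf(n: int, w: float) -> tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) under H0 for untied ranks 1..n."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[: max_w + 1 - r].copy()
    total = counts.sum()
    wi = int(round(w))
    cdf = counts[: wi + 1].sum() / total
    sf = counts[wi:].sum() / total
    return cdf, sf


def wilcoxon_signed_rank(x, y) -> tuple[float, float, int, bool]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are discarded (standard convention).  Returns
    ``(W, p, n_effective, exact)`` where ``W = min(W+, W−)``.  The exact
    permutation null is used for 1 ≤ n ≤ 25 without ties in |d|;
    otherwise the normal approximation with tie correction and a 0.5
    continuity correction.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, 0, True
    ranks = _stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    has_ties = np.unique(np.abs(d)).size != n
    if n <= 25 and not has_ties:
        cdf, sf = _exact_wplus_sf_cdf(n, w_plus)
        p = min(1.0, 2.0 * min(cdf, sf))
        return w, p, n, True
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    if has_ties:
        _, counts = np.unique(np.abs(d), return_counts=True)
        var -= (counts**3 - counts).sum() / 48.0
    if var == 0:
        return w, 1.0, n, False
    z = (w - mean + 0.5) / np.sqrt(var)  # continuity-corrected, lower tail
    p = min(1.0, 2.0 * _stats.norm.cdf(z))
    return w, p, n, False


# ---------------------------------------------------------------------------
# normality-gated paired comparison
# ---------------------------------------------------------------------------


def paired_compare(
    x, y, alpha: float = ALPHA, gate: str = "differences"
) -> PairedTestResult:
    """Shapiro–Wilk-gated paired comparison of two matched samples.

    ``gate='differences'`` (default) tests normality of the paired
    differences — the quantity the t-test actually assumes normal;
    ``gate='both'`` requires both samples to pass.  If normality is not
    rejected at ``alpha`` a two-sided paired t-test is used, otherwise
    the two-sided Wilcoxon signed-rank test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if x.size < 5:
        raise ValueError(f"need at least 5 pairs, got {x.size}")
    d = x - y
    if np.all(d == 0):
        return PairedTestResult(
            test_name="degenerate",
            statistic=0.0,
            p_value=1.0,
            n_pairs=x.size,
            normality_p_values=(float("nan"),),
            degenerate=True,
        )
    if gate == "differences":
        sw = (_stats.shapiro(d).pvalue,)
    elif gate == "both":
        sw = (_stats.shapiro(x).pvalue, _stats.shapiro(y).pvalue)
    else:
        raise ValueError(f"unknown gate {gate!r}")
    normal = all(p > alpha for p in sw)
    if normal:
        t = _stats.ttest_rel(x, y)
        return PairedTestResult("t_paired", float(t.statistic), float(t.pvalue),
                                x.size, tuple(float(p) for p in sw))
    w, p, n_eff, _ = wilcoxon_signed_rank(x, y)
    return PairedTestResult("wilcoxon_signed_rank", w, p, x.size,
                            tuple(float(p) for p in sw))


# ---------------------------------------------------------------------------
# repeated-measures correlation
# ---------------------------------------------------------------------------


def rmcorr(subjects, x, y) -> RmcorrResult:
    """Repeated-measures correlation via the common-slope ANCOVA model.

    ``subjects`` labels each paired observation; subjects contributing
    fewer than 2 observations, or constant ``x``, add no slope
    information and are dropped.  ``r`` is the Pearson correlation of
    the within-subject-centred data (identically
    ``sign(slope)·sqrt(SS_measure / (SS_measure + SS_error))`` from the
    ANCOVA decomposition); ``dof = N_obs − N_subjects − 1``.
    """
    subjects = np.asarray(subjects)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (subjects.shape == x.shape == y.shape):
        raise ValueError("subjects, x and y must align")
    xc, yc = [], []
    n_subj = 0
    n_obs = 0
    for s in pd.unique(subjects):
        sel = subjects == s
        if sel.sum() < 2 or np.ptp(x[sel]) == 0:
            continue
        n_subj += 1
        n_obs += int(sel.sum())
        xc.append(x[sel] - x[sel].mean())
        yc.append(y[sel] - y[sel].mean())
    if n_subj < 3:
        raise ValueError("need at least 3 subjects with >= 2 varying observations each")
    xc = np.concatenate(xc)
    yc = np.concatenate(yc)
    ss_x = float(xc @ xc)
    ss_y = float(yc @ yc)
    if ss_y == 0:
        raise ValueError("y has no within-subject variation")
    r = float(xc @ yc / np.sqrt(ss_x * ss_y))
    r = float(np.clip(r, -1.0, 1.0))
    dof = n_obs - n_subj - 1
    if dof < 1:
        raise ValueError("not enough observations for the rmcorr dof")
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r * r))
        p = float(2.0 * _stats.t.sf(abs(t), dof))
    return RmcorrResult(r=r, dof=dof, p_value=p, n_subjects=n_subj, n_obs=n_obs)


# ---------------------------------------------------------------------------
# percentage difference
# ---------------------------------------------------------------------------


def percent_difference(video_values, lab_values) -> float:
    """Mean over subjects of |video − lab| / |lab| × 100.

    Pairs whose laboratory value is zero are excluded (with a warning)
    rather than producing an infinite percentage.
    """
    import warnings

    v = np.asarray(video_values, dtype=float)
    l = np.asarray(lab_values, dtype=float)
    if v.shape != l.shape or v.ndim != 1:
        raise ValueError("video and laboratory values must be paired 1-D arrays")
    keep = l != 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} pair(s) with zero laboratory value",
            RuntimeWarning,
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("no pairs with non-zero laboratory value")
    return float(np.mean(np.abs(v[keep] - l[keep]) / np.abs(l[keep])) * 100.0)
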