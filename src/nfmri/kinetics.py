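"""Serial no-flow kinetics and cohort-comparison statistics.

The serial analysis treats the first post-contrast measurement (2 min,
early-enhancement imaging) as the reference and asks at which later
timepoint the no-flow volume becomes — and stays — significantly smaller:
a one-way within-subject (repeated-measures) ANOVA gates paired t tests of
each timepoint against the reference, Holm-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantification import mask_volume
from .segmentation import RegionMasks


@dataclass
class KineticsSeries:
    """One subject's NF (and total-MI) volume per post-contrast minute."""

    subject_id: str
    group: str  # "reperfused" | "non-reperfused"
    nf_volume_ml: dict = field(default_factory=dict)      # minute -> ml
    mi_volume_ml: dict = field(default_factory=dict)
    reference_min: float = 2.0

    def __post_init__(self):
        if self.reference_min not in {float(t) for t in self.nf_volume_ml}:
            raise ValueError(
                f"reference timepoint {self.reference_min} min missing from the series")

    def to_frame(self) -> pd.DataFrame:
        ts = sorted(self.nf_volume_ml)
        return pd.DataFrame({
            "subject": self.subject_id,
            "group": self.group,
            "timepoint_min": ts,
            "nf_volume_ml": [self.nf_volume_ml[t] for t in ts],
            "mi_volume_ml": [self.mi_volume_ml.get(t, np.nan) for t in ts],
        })


def nf_timecourse(masks_by_timepoint: dict, subject_id: str = "phantom",
                  group: str = "reperfused", reference_min: float = 2.0) -> KineticsSeries:
    """Volumes over the post-contrast schedule from per-timepoint segmentations.

    ``masks_by_timepoint`` maps minute -> RegionMasks.  Total-MI volume is
    tracked alongside NF (it should stay constant over the session).
    """
    nf, mi = {}, {}
    for t, m in masks_by_timepoint.items():
        if not isinstance(m, RegionMasks):
            raise TypeError("expected RegionMasks per timepoint")
        nf[float(t)] = mask_volume(m.nf, m.pixel_spacing_mm, m.slice_thickness_mm)
        mi[float(t)] = mask_volume(m.total_mi, m.pixel_spacing_mm, m.slice_thickness_mm)
    return KineticsSeries(subject_id=subject_id, group=group, nf_volume_ml=nf,
                          mi_volume_ml=mi, reference_min=reference_min)


# ---------------------------------------------------------------------------
# statistics


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float


@dataclass(frozen=True)
class RmAnovaResult:
    f_statistic: float
    df_time: int
    df_error: int
    p_value: float


def rm_anova_oneway(data: np.ndarray) -> RmAnovaResult:
    """One-way within-subject ANOVA on a complete subjects x timepoints matrix.

    F = MS_time / MS_(time x subject), df = (t-1, (t-1)(s-1)).  Degenerate
    inputs follow explicit contracts: a matrix with no time effect at all
    gives F = 0, p = 1; a perfectly consistent nonzero effect (zero residual)
    gives F = inf, p = 0.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 subjects and >= 2 timepoints")
    if not np.all(np.isfinite(data)):
        raise ValueError("matrix has missing cells; no imputation is performed")
    s, t = data.shape
    grand = data.mean()
    time_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_time = s * float(((time_means - grand) ** 2).sum())
    resid = data - time_means[None, :] - subj_means[:, None] + grand
    ss_err = float((resid ** 2).sum())
    df1, df2 = t - 1, (t - 1) * (s - 1)
    if ss_time <= 1e-12 * max(1.0, abs(grand)) ** 2:
        return RmAnovaResult(0.0, df1, df2, 1.0)
    if ss_err <= 1e-12 * ss_time:
        return RmAnovaResult(float("inf"), df1, df2, 0.0)
    f = (ss_time / df1) / (ss_err / df2)
    p = float(stats.f.sf(f, df1, df2))
    return RmAnovaResult(float(f), df1, df2, p)


def paired_t(a, b) -> TestResult:
    """Paired-samples t test; identical samples give t = 0, p = 1, not NaN."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired test needs two equal-length samples of n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return TestResult(0.0, len(a) - 1, 1.0)
        return TestResult(float("inf") * np.sign(d.mean()), len(a) - 1, 0.0)
    res = stats.ttest_rel(a, b)
    return TestResult(float(res.statistic), float(len(a) - 1), float(res.pvalue))


def independent_t(a, b, welch: bool = False) -> TestResult:
    """Two-sample t test, pooled-variance by default (Welch by flag)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) < 2 or len(b) < 2:
        raise ValueError("independent test needs two samples of n >= 2")
    if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
        df = len(a) + len(b) - 2
        if np.allclose(a.mean(), b.mean()):
            return TestResult(0.0, df, 1.0)
        return TestResult(float("inf") * np.sign(a.mean() - b.mean()), df, 0.0)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else float(len(a) + len(b) - 2)
    return TestResult(float(res.statistic), df, float(res.pvalue))


def ks_normality(x) -> TestResult:
    """Kolmogorov-Smirnov distance of the sample from N(mean, sd).

    Location and scale are estimated from the sample (as clinical statistics
    packages apply the test), which makes the p value conservative; the
    methods note documents the caveat.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("normality test needs a 1-D sample of n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("sample has zero variance")
    res = stats.kstest(x, "norm", args=(x.mean(), sd))
    return TestResult(float(res.statistic), float(len(x)), float(res.pvalue))


def first_significant_timepoint(data: np.ndarray, timepoints, reference_min: float = 2.0,
                                alpha: float = 0.05, correction: str = "holm"):
    """Earliest timepoint significantly different from the reference, sustained.

    ``data`` is subjects x timepoints (complete).  The repeated-measures ANOVA
    gates the procedure; each non-reference timepoint is then compared to the
    reference by a paired t test and the p values corrected (Holm by
    default).  Returns the earliest timepoint that is significant with every
    later timepoint also significant ("and thereafter"), or None.
    """
    data = np.asarray(data, dtype=float)
    timepoints = [float(t) for t in timepoints]
    if data.ndim != 2 or data.shape[1] != len(timepoints):
        raise ValueError("data columns must match the timepoint list")
    if data.shape[0] < 2:
        raise ValueError("paired comparisons are undefined for a single subject")
    if reference_min not in timepoints:
        raise ValueError(f"reference timepoint {reference_min} not in {timepoints}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    anova = rm_anova_oneway(data)
    if not anova.p_value < alpha:
        return None
    ref_idx = timepoints.index(reference_min)
    others = [i for i in range(len(timepoints)) if i != ref_idx]
    pvals = [paired_t(data[:, i], data[:, ref_idx]).p_value for i in others]
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method=correction)
    later = [i for i in others if timepoints[i] > reference_min]
    flags = {i: r for i, r in zip(others, reject)}
    for pos, i in enumerate(later):
        if all(flags[j] for j in later[pos:]) and flags[i]:
            return timepoints[i]
    return None


def compare_groups(a: pd.DataFrame, b: pd.DataFrame, columns=None,
                   welch: bool = False) -> pd.DataFrame:
    """Independent-samples comparison of per-subject metric tables."""
    if columns is None:
        columns = [c for c in a.columns if c in b.columns
                   and np.issubdtype(a[c].dtype, np.number)]
    rows = []
    for c in columns:
        res = independent_t(a[c].to_numpy(), b[c].to_numpy(), welch=welch)
        rows.append({"metric": c, "mean_a": a[c].mean(), "sd_a": a[c].std(ddof=1),
                     "mean_b": b[c].mean(), "sd_b": b[c].std(ddof=1),
                     "t": res.statistic, "df": res.df, "p": res.p_value})
    return pd.DataFrame(rows)


def plot_nf_timecourse(series_list, ax=None):
    """Group-mean NF volume against post-contrast time (one line per series)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for series in series_list:
        ts = sorted(series.nf_volume_ml)
        ax.plot(ts, [series.nf_volume_ml[t] for t in ts], marker="o",
                label=f"{series.subject_id} ({series.group})")
    ax.set_xlabel("time after contrast (min)")
    ax.set_ylabel("NF volume (ml)")
    ax.legend(fontsize=7)
    return ax
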