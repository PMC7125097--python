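"""Cohort-level statistics: paired above/below-LLA summaries, index
variability, paired ROC with the DeLong test, and agreement analyses.

The study design is paired within animal: each recording contributes one
mean index value for all epochs with ABP above its LLA and one for all
epochs below it, for each of the six indices.  ROC analyses therefore
operate on these per-animal means (two observations per animal), not on
pooled epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.proportion import proportion_confint

from .correlation import IndexSeries
from .errors import DegenerateVarianceError, InputError
from .preprocess import SlowWaveSeries


@dataclass
class PairedSummary:
    """One animal's above/below-LLA mean for one index."""

    index_name: str
    mean_above: float          # NaN if no epochs on that side
    mean_below: float
    n_above: int
    n_below: int
    one_sided: bool            # flagged when either side had no data


@dataclass
class ROCResult:
    auc: float
    auc_se: float
    auc_p_vs_chance: float     # DeLong-variance z test of AUC = 0.5
    cutoff: float              # score threshold maximizing Youden J
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass
class AgreementResult:
    r: float
    r_p: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float


def paired_above_below(
    index: IndexSeries, series: SlowWaveSeries, lla: float, abp_ch: str = "abp"
) -> PairedSummary:
    """Mean index over epochs with concurrent ABP above vs below the LLA."""
    if len(index) != len(series):
        raise InputError("index and series are not aligned")
    abp = series[abp_ch]
    v = index.values
    ok = np.isfinite(abp) & np.isfinite(v)
    above = ok & (abp > lla)
    below = ok & (abp <= lla)
    return PairedSummary(
        index_name=index.name,
        mean_above=float(v[above].mean()) if above.any() else float("nan"),
        mean_below=float(v[below].mean()) if below.any() else float("nan"),
        n_above=int(above.sum()),
        n_below=int(below.sum()),
        one_sided=not (above.any() and below.any()),
    )


def index_sd_above(
    index: IndexSeries, series: SlowWaveSeries, lla: float, abp_ch: str = "abp"
) -> float:
    """Standard deviation of the index over above-LLA epochs (one per animal)."""
    abp = series[abp_ch]
    v = index.values
    ok = np.isfinite(abp) & np.isfinite(v) & (abp > lla)
    if ok.sum() < 2:
        return float("nan")
    return float(v[ok].std(ddof=1))


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative).

    Uses the midrank formulation; ties get half credit.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = s[y], s[~y]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise InputError("both classes must be present")
    # psi(X_i, Y_j) matrix averaged per row / per column
    cmp_mat = (pos[:, None] > neg[None, :]).astype(float)
    cmp_mat += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_mat.mean(axis=1)
    v01 = cmp_mat.mean(axis=0)
    return v10, v01


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the pairwise concordance probability (half credit for ties)."""
    v10, _ = _structural_components(scores, labels)
    return float(v10.mean())


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of one AUC estimate."""
    v10, v01 = _structural_components(scores, labels)
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise InputError("need at least 2 observations per class")
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def roc_with_cutoff(scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05) -> ROCResult:
    """ROC curve with AUC, Youden-J cutoff and exact binomial CIs.

    ``labels`` are True for the positive class (here: below-LLA).  The cutoff
    classifies ``score >= cutoff`` as positive.  Sensitivity/specificity CIs
    are Clopper-Pearson.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise InputError("both classes must be present")
    auc = float(roc_auc_score(y, s))
    var = delong_variance(s, y)
    se = float(np.sqrt(var))
    z = (auc - 0.5) / se if se > 0 else np.inf
    p_chance = float(2 * stats.norm.sf(abs(z)))

    fpr, tpr, thr = roc_curve(y, s)
    j = tpr - fpr
    k = int(np.argmax(j))
    cutoff = float(thr[k])
    pred_pos = s >= cutoff
    tp = int((pred_pos & y).sum())
    tn = int((~pred_pos & ~y).sum())
    m, n = int(y.sum()), int((~y).sum())
    sens = tp / m
    spec = tn / n
    sens_ci = proportion_confint(tp, m, alpha=alpha, method="beta")
    spec_ci = proportion_confint(tn, n, alpha=alpha, method="beta")
    return ROCResult(
        auc=auc,
        auc_se=se,
        auc_p_vs_chance=p_chance,
        cutoff=cutoff,
        sensitivity=float(sens),
        sensitivity_ci=(float(sens_ci[0]), float(sens_ci[1])),
        specificity=float(spec),
        specificity_ci=(float(spec_ci[0]), float(spec_ci[1])),
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
    )


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """DeLong test for two correlated ROC curves on the same observations.

    Returns ``(auc_a - auc_b, z, two-sided p)``.  Identical scores give
    ``(0, 0, 1)``; a zero variance with a nonzero difference is degenerate.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if a.shape != b.shape or a.shape != y.shape:
        raise InputError("scores and labels must be aligned")
    v10a, v01a = _structural_components(a, y)
    v10b, v01b = _structural_components(b, y)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = len(v10a), len(v01a)
    if m < 2 or n < 2:
        raise InputError("need at least 2 observations per class")
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = float(auc_a - auc_b)
    if var <= 0:
        if abs(diff) < 1e-15:
            return 0.0, 0.0, 1.0
        raise DegenerateVarianceError(
            f"zero DeLong variance with nonzero AUC difference {diff:.3g}"
        )
    z = diff / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return diff, float(z), p


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Classical paired t test on ``x - y`` (two-sided).

    ``x == y`` returns ``(0, 1)``; a constant nonzero difference is
    degenerate (zero variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise InputError("need equal-length vectors of length >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d[0] == 0.0:
            return 0.0, 1.0
        raise DegenerateVarianceError("constant nonzero paired difference")
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)


def bland_altman(a: np.ndarray, b: np.ndarray) -> AgreementResult:
    """Agreement between two paired measurements: Pearson r plus
    Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 SD)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise InputError("need paired vectors of length >= 3")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r, rp = float("nan"), float("nan")
    else:
        r, rp = stats.pearsonr(a, b)
    return AgreementResult(
        r=float(r),
        r_p=float(rp),
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )
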