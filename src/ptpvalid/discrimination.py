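"""Discrimination statistics: ROC AUC with DeLong variance, paired AUC
comparison, and the integrated discrimination improvement (IDI).

The AUC is the Mann-Whitney probability that a randomly chosen diseased
individual scores above a randomly chosen non-diseased one (ties counted
half).  Its variance, and the covariance between two models scored on the
same individuals, use DeLong's structural components (placement values),
computed via midranks.  The IDI is the difference of discrimination slopes:
the gain in mean predicted probability among events minus the gain among
non-events when switching models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AucEstimate",
    "AucComparison",
    "IdiResult",
    "DiscriminationError",
    "auc",
    "delong_compare",
    "idi",
    "idi_from_group_means",
    "roc_points",
]


class DiscriminationError(ValueError):
    """Undefined or degenerate discrimination statistic."""


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    n_pos: int
    n_neg: int
    variance: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class AucComparison:
    auc_a: float
    auc_b: float
    diff: float  # auc_b - auc_a
    z: float
    p_value: float


@dataclass(frozen=True)
class IdiResult:
    mean_pos_old: float
    mean_pos_new: float
    mean_neg_old: float
    mean_neg_new: float
    idi: float
    z: float
    p_value: float


def _validate_scores(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=bool)
    if scores.shape != y.shape or scores.ndim != 1:
        raise DiscriminationError("scores and labels must be aligned 1-d vectors")
    if not (y.any() and (~y).any()):
        raise DiscriminationError("AUC undefined: both classes must be present")
    if np.isnan(scores).any():
        raise DiscriminationError("scores contain NaN")
    return scores, y


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement values via midranks.

    Returns (auc, v10, v01): v10[i] is the fraction of negatives that
    positive i outranks (ties half), v01[j] the complement for negative j.
    """
    pos, neg = scores[y], scores[~y]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    a = float(v10.mean())
    return a, v10, v01


def auc(scores, y) -> AucEstimate:
    """Mann-Whitney AUC with DeLong variance and a Wald 95% CI.

    The CI is truncated to [0, 1]; variance is exactly zero only for
    perfectly separated or fully tied data.
    """
    scores, y = _validate_scores(np.asarray(scores), np.asarray(y))
    a, v10, v01 = _placements(scores, y)
    m, n = len(v10), len(v01)
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (max(0.0, a - half), min(1.0, a + half))
    return AucEstimate(auc=a, n_pos=m, n_neg=n, variance=var, ci95=ci)


def delong_compare(scores_a, scores_b, y) -> AucComparison:
    """Paired comparison of two models' AUCs on the same individuals.

    z = (auc_b - auc_a) / sqrt(var_a + var_b - 2 cov) with variances and
    covariance from the DeLong placement values; two-sided normal p.
    """
    scores_a, ya = _validate_scores(np.asarray(scores_a), np.asarray(y))
    scores_b, yb = _validate_scores(np.asarray(scores_b), np.asarray(y))
    a_a, v10a, v01a = _placements(scores_a, ya)
    a_b, v10b, v01b = _placements(scores_b, yb)
    m, n = len(v10a), len(v01a)
    diff = a_b - a_a

    if m > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    cov_mat = s10 / m + s01 / n
    var_diff = cov_mat[0, 0] + cov_mat[1, 1] - 2.0 * cov_mat[0, 1]
    if var_diff <= 0.0:
        if diff == 0.0:
            # identical placement structure: no evidence of a difference
            return AucComparison(a_a, a_b, 0.0, 0.0, 1.0)
        raise DiscriminationError(
            "degenerate paired comparison: zero variance of the AUC difference"
        )
    z = diff / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return AucComparison(auc_a=a_a, auc_b=a_b, diff=diff, z=float(z), p_value=float(p))


def idi(p_old, p_new, y) -> IdiResult:
    """Integrated discrimination improvement of the new model over the old.

    idi = (mean_pos_new - mean_pos_old) - (mean_neg_new - mean_neg_old);
    significance by an asymptotic z on the paired per-record differences,
    with the standard error pooled over positives and negatives.
    """
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    y = np.asarray(y, dtype=bool)
    if not (p_old.shape == p_new.shape == y.shape):
        raise DiscriminationError("inputs must be aligned vectors")
    if not (y.any() and (~y).any()):
        raise DiscriminationError("IDI undefined: both classes must be present")
    d = p_new - p_old
    d_pos, d_neg = d[y], d[~y]
    m, n = len(d_pos), len(d_neg)
    idi_val = float(d_pos.mean() - d_neg.mean())
    se2 = (np.var(d_pos, ddof=1) / m if m > 1 else 0.0) + (
        np.var(d_neg, ddof=1) / n if n > 1 else 0.0
    )
    if se2 > 0:
        z = idi_val / np.sqrt(se2)
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        z, p = (0.0, 1.0) if idi_val == 0.0 else (np.inf * np.sign(idi_val), 0.0)
    return IdiResult(
        mean_pos_old=float(p_old[y].mean()),
        mean_pos_new=float(p_new[y].mean()),
        mean_neg_old=float(p_old[~y].mean()),
        mean_neg_new=float(p_new[~y].mean()),
        idi=idi_val,
        z=float(z),
        p_value=p,
    )


def idi_from_group_means(
    mean_pos_old: float, mean_neg_old: float, mean_pos_new: float, mean_neg_new: float
) -> float:
    """IDI recomputed from published group-mean PTPs.

    (mean_pos_new - mean_pos_old) - (mean_neg_new - mean_neg_old); lets the
    printed decomposition of a discrimination table be checked directly.
    """
    vals = (mean_pos_old, mean_neg_old, mean_pos_new, mean_neg_new)
    if any(not (0.0 <= v <= 1.0) for v in vals):
        raise DiscriminationError(f"group means must be probabilities, got {vals}")
    return (mean_pos_new - mean_pos_old) - (mean_neg_new - mean_neg_old)


def roc_points(scores, y) -> np.ndarray:
    """(FPR, TPR) pairs at every distinct threshold, for export/plotting."""
    scores, y = _validate_scores(np.asarray(scores), np.asarray(y))
    order = np.argsort(-scores, kind="mergesort")
    s, lab = scores[order], y[order].astype(float)
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(lab)[distinct]
    fp = np.cumsum(1.0 - lab)[distinct]
    tpr = np.r_[0.0, tp / lab.sum()]
    fpr = np.r_[0.0, fp / (len(lab) - lab.sum())]
    return np.column_stack([fpr, tpr])
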