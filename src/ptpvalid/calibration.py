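"""Decile-based calibration and the Hosmer-Lemeshow chi-square test.

Individuals are grouped by quantiles of predicted probability (deciles by
default); in each group the observed event count O is compared with the
expected count E = sum of predictions.  The statistic

    chi2 = sum_g (O_g - E_g)^2 / (E_g * (1 - pbar_g))

with pbar_g the mean prediction in group g (equivalently the classical
n_g * pbar_g * (1 - pbar_g) denominator) is referred to a chi-square
distribution.  The default degrees of freedom follow the common
fitted-model convention g - 2; when the probabilities are externally
specified (a published model applied without refitting, or simulation truth)
the group deviations are independent and the correct reference has g degrees
of freedom, selectable via the ``df`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DecileCalibration",
    "HlResult",
    "CalibrationError",
    "decile_groups",
    "hosmer_lemeshow",
    "calibration_curve_data",
]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class DecileCalibration:
    """Per-group calibration summary, ordered by predicted probability."""

    n: np.ndarray  # group sizes
    mean_predicted: np.ndarray
    observed_rate: np.ndarray
    expected_events: np.ndarray
    boundaries: np.ndarray  # interior quantile cut points

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                group=np.arange(len(self.n)),
                n=self.n,
                mean_predicted=self.mean_predicted,
                observed_rate=self.observed_rate,
                expected_events=self.expected_events,
            )
        )


@dataclass(frozen=True)
class HlResult:
    chi2: float
    df: int
    p_value: float
    groups: DecileCalibration


def decile_groups(p, g: int = 10) -> np.ndarray:
    """Quantile-based group assignment (0..g-1) by predicted probability.

    Cut points are the interior quantiles of p; a value exactly equal to a
    cut point goes to the lower group, so assignment is deterministic and
    order-independent.  Under heavy ties several nominal groups may be empty
    and the populated groups correspondingly larger.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise CalibrationError("p must be a 1-d vector")
    if g < 1:
        raise CalibrationError("need at least one group")
    if len(p) < g:
        raise CalibrationError(
            f"n={len(p)} < g={g}; use fewer groups"
        )
    if g == 1:
        return np.zeros(len(p), dtype=np.int64)
    breaks = np.quantile(p, np.arange(1, g) / g)
    # count of cut points strictly below each value -> ties fall to the lower group
    return np.searchsorted(breaks, p, side="left").astype(np.int64)


def _group_summary(p: np.ndarray, y: np.ndarray, assign: np.ndarray, g: int) -> DecileCalibration:
    n = np.bincount(assign, minlength=g).astype(np.int64)
    nonempty = n > 0
    sum_p = np.bincount(assign, weights=p, minlength=g)
    sum_y = np.bincount(assign, weights=y.astype(float), minlength=g)
    with np.errstate(invalid="ignore"):
        mean_p = np.where(nonempty, sum_p / np.maximum(n, 1), np.nan)
        obs = np.where(nonempty, sum_y / np.maximum(n, 1), np.nan)
    breaks = np.quantile(p, np.arange(1, g) / g) if g > 1 else np.empty(0)
    return DecileCalibration(
        n=n[nonempty],
        mean_predicted=mean_p[nonempty],
        observed_rate=obs[nonempty],
        expected_events=sum_p[nonempty],
        boundaries=breaks,
    )


def calibration_curve_data(p, y, g: int = 10) -> DecileCalibration:
    """Observed vs predicted event rates by quantile group, for plotting."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=bool)
    if p.shape != y.shape:
        raise CalibrationError("p and y must be aligned")
    assign = decile_groups(p, g)
    return _group_summary(p, y, assign, g)


def hosmer_lemeshow(p, y, g: int = 10, df: int | None = None) -> HlResult:
    """Hosmer-Lemeshow goodness-of-fit test on quantile groups of p.

    Requires at least three populated groups (default df = groups - 2 >= 1)
    and no degenerate cell (expected events equal to 0 or to the whole
    group).  Pass ``df=k`` (k populated groups) when the probabilities were
    not estimated from these data.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=bool)
    if p.shape != y.shape:
        raise CalibrationError("p and y must be aligned")
    if not (y.any() and (~y).any()):
        raise CalibrationError("both outcome classes must be present")
    cal = calibration_curve_data(p, y, g)
    k = len(cal.n)
    if k < 3:
        raise CalibrationError(
            f"degenerate grouping: only {k} populated group(s); "
            "predictions too heavily tied for a Hosmer-Lemeshow test"
        )
    e = cal.expected_events
    n_g = cal.n.astype(float)
    if np.any(e <= 0) or np.any(e >= n_g):
        raise CalibrationError("degenerate cell: a group has expected events 0 or n")
    o = cal.observed_rate * n_g
    pbar = cal.mean_predicted
    chi2 = float(np.sum((o - e) ** 2 / (e * (1.0 - pbar))))
    if df is None:
        df = k - 2
    if df < 1:
        raise CalibrationError(f"df must be >= 1, got {df}")
    p_value = float(stats.chi2.sf(chi2, df))
    return HlResult(chi2=chi2, df=df, p_value=p_value, groups=cal)
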