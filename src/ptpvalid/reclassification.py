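"""Guideline PTP categories and the categorical net reclassification
improvement (NRI), with full reclassification tables.

Individuals are binned at the guideline cut-offs into low (<15%), medium
(15-85%, both boundaries inclusive) and high (>85%) pretest probability.
Switching models moves individuals between categories; the categorical NRI
credits events moved up and non-events moved down:

    NRI = [P(up|event) - P(down|event)] + [P(down|non-event) - P(up|non-event)]
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from fractions import Fraction

import numpy as np
from scipy import stats

__all__ = [
    "PtpCategory",
    "ReclassificationTable",
    "NriResult",
    "ReclassificationError",
    "DEFAULT_CUTOFFS",
    "assign_ptp_category",
    "assign_ptp_categories",
    "build_reclassification_table",
    "nri_from_table",
    "nri",
]

DEFAULT_CUTOFFS = (0.15, 0.85)


class ReclassificationError(ValueError):
    pass


class PtpCategory(IntEnum):
    """Ordered guideline PTP category; the integer value is the rank."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2


@dataclass(frozen=True)
class ReclassificationTable:
    """3x3 cross-classification of PTP categories, rows = new-model category,
    columns = old-model category, stratified by outcome."""

    counts_pos: np.ndarray
    counts_neg: np.ndarray

    def __post_init__(self) -> None:
        for name, m in (("counts_pos", self.counts_pos), ("counts_neg", self.counts_neg)):
            m = np.asarray(m)
            if m.shape != (3, 3) or (m < 0).any() or not np.issubdtype(m.dtype, np.integer):
                raise ReclassificationError(f"{name} must be a 3x3 nonnegative integer matrix")
        object.__setattr__(self, "counts_pos", np.asarray(self.counts_pos, dtype=np.int64))
        object.__setattr__(self, "counts_neg", np.asarray(self.counts_neg, dtype=np.int64))

    @property
    def n_pos(self) -> int:
        return int(self.counts_pos.sum())

    @property
    def n_neg(self) -> int:
        return int(self.counts_neg.sum())


@dataclass(frozen=True)
class NriResult:
    up_pos: int
    down_pos: int
    up_neg: int
    down_neg: int
    p_up_pos: float
    p_down_pos: float
    p_up_neg: float
    p_down_neg: float
    nri_pos: float
    nri_neg: float
    nri_overall: float
    z: float
    p_value: float


def assign_ptp_category(
    ptp: float, cutoffs: tuple[float, float] = DEFAULT_CUTOFFS
) -> PtpCategory:
    """Guideline category for one PTP; the boundaries belong to medium."""
    lo, hi = cutoffs
    if not (0.0 <= ptp <= 1.0):
        raise ReclassificationError(f"ptp outside [0,1]: {ptp}")
    if ptp < lo:
        return PtpCategory.LOW
    if ptp <= hi:
        return PtpCategory.MEDIUM
    return PtpCategory.HIGH


def assign_ptp_categories(
    ptp, cutoffs: tuple[float, float] = DEFAULT_CUTOFFS
) -> np.ndarray:
    """Vectorized category assignment; returns integer ranks 0/1/2."""
    p = np.asarray(ptp, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ReclassificationError("ptp values outside [0,1]")
    lo, hi = cutoffs
    return np.where(p < lo, 0, np.where(p <= hi, 1, 2)).astype(np.int64)


def build_reclassification_table(cats_old, cats_new, y) -> ReclassificationTable:
    """Tally the 3x3 new-by-old category matrices for events and non-events."""
    co = np.asarray(cats_old, dtype=np.int64)
    cn = np.asarray(cats_new, dtype=np.int64)
    yy = np.asarray(y, dtype=bool)
    if not (co.shape == cn.shape == yy.shape):
        raise ReclassificationError("category and outcome vectors must be aligned")
    mats = []
    for mask in (yy, ~yy):
        m = np.zeros((3, 3), dtype=np.int64)
        np.add.at(m, (cn[mask], co[mask]), 1)
        mats.append(m)
    return ReclassificationTable(counts_pos=mats[0], counts_neg=mats[1])


def _up_down(m: np.ndarray) -> tuple[int, int]:
    """(up, down) counts: up = new rank > old rank (below-diagonal cells,
    rows being the new category), down = new < old (above-diagonal)."""
    up = int(np.tril(m, -1).sum())
    down = int(np.triu(m, 1).sum())
    return up, down


def nri_from_table(t: ReclassificationTable) -> NriResult:
    """Categorical NRI with its asymptotic z-test from a reclassification table.

    Components are computed in rational arithmetic so nri_overall equals
    nri_pos + nri_neg exactly before any rounding.  The variance treats the
    up/down moves in each outcome stratum as a paired multinomial:
    var = (p_up + p_down - (p_up - p_down)^2) / n per stratum, summed.
    """
    if t.n_pos == 0 or t.n_neg == 0:
        raise ReclassificationError("NRI undefined: empty outcome stratum")
    up_pos, down_pos = _up_down(t.counts_pos)
    up_neg, down_neg = _up_down(t.counts_neg)
    npos, nneg = t.n_pos, t.n_neg
    nri_pos = Fraction(up_pos - down_pos, npos)
    nri_neg = Fraction(down_neg - up_neg, nneg)
    overall = nri_pos + nri_neg

    var_pos = (up_pos + down_pos) / npos**2 - (up_pos - down_pos) ** 2 / npos**3
    var_neg = (up_neg + down_neg) / nneg**2 - (down_neg - up_neg) ** 2 / nneg**3
    var = var_pos + var_neg
    if var > 0:
        z = float(overall) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        z, p = (0.0, 1.0) if overall == 0 else (np.inf * np.sign(float(overall)), 0.0)
    return NriResult(
        up_pos=up_pos,
        down_pos=down_pos,
        up_neg=up_neg,
        down_neg=down_neg,
        p_up_pos=up_pos / npos,
        p_down_pos=down_pos / npos,
        p_up_neg=up_neg / nneg,
        p_down_neg=down_neg / nneg,
        nri_pos=float(nri_pos),
        nri_neg=float(nri_neg),
        nri_overall=float(overall),
        z=float(z),
        p_value=p,
    )


def nri(
    p_old, p_new, y, cutoffs: tuple[float, float] = DEFAULT_CUTOFFS
) -> tuple[ReclassificationTable, NriResult]:
    """Categorical NRI of the new model over the old from raw PTP vectors."""
    cats_old = assign_ptp_categories(p_old, cutoffs)
    cats_new = assign_ptp_categories(p_new, cutoffs)
    table = build_reclassification_table(cats_old, cats_new, y)
    return table, nri_from_table(table)
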