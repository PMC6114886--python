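"""Diagnostic-strategy impact of switching PTP models.

Guideline strategies follow the PTP category: low -> no further testing,
medium -> noninvasive testing (e.g. CCTA or exercise testing), high ->
invasive strategy.  The headline quantity is unnecessary testing avoided:
CAD-negative individuals whom the old model placed in the medium category
(noninvasive testing recommended) and the new model moves to low (no further
test).  Positives moving down are tallied separately as potential harms.
Event rates among the moved individuals quantify the safety of the change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .cohort import CohortTable, EventKind, PatientRecord, classify_mace
from .reclassification import PtpCategory

__all__ = [
    "STRATEGY_MAP",
    "StratumImpact",
    "ImpactSummary",
    "EventTally",
    "StrategyError",
    "strategy_changes",
    "events_among",
]

# Total mapping from PTP category to guideline diagnostic strategy.
STRATEGY_MAP = {
    PtpCategory.LOW: "no_further_test",
    PtpCategory.MEDIUM: "noninvasive_test",
    PtpCategory.HIGH: "invasive_strategy",
}


class StrategyError(ValueError):
    pass


@dataclass(frozen=True)
class StratumImpact:
    stratum: str
    n_old_medium_neg: int
    n_moved_to_low_neg: int
    n_moved_to_low_pos: int  # positives losing a testing recommendation: potential harm

    @property
    def fraction_moved(self) -> float:
        if self.n_old_medium_neg == 0:
            raise StrategyError("no old-medium negatives; fraction undefined")
        return self.n_moved_to_low_neg / self.n_old_medium_neg


@dataclass(frozen=True)
class ImpactSummary:
    strata: tuple[StratumImpact, ...]

    @property
    def pooled_moved(self) -> int:
        return sum(s.n_moved_to_low_neg for s in self.strata)

    @property
    def pooled_old_medium_neg(self) -> int:
        return sum(s.n_old_medium_neg for s in self.strata)


@dataclass(frozen=True)
class EventTally:
    n: int
    n_followed: int
    n_excluded_no_followup: int
    mace_count: int
    mace_rate: float
    breakdown: dict[str, int]


def strategy_changes(
    cats_old, cats_new, y, strata: Optional[Sequence[str]] = None
) -> ImpactSummary:
    """Count negatives whose recommendation changes from noninvasive testing
    to no further test when switching models, per stratum and pooled."""
    co = np.asarray(cats_old, dtype=np.int64)
    cn = np.asarray(cats_new, dtype=np.int64)
    yy = np.asarray(y, dtype=bool)
    if not (co.shape == cn.shape == yy.shape):
        raise StrategyError("inputs must be aligned vectors")
    labels = np.asarray(["all"] * len(co) if strata is None else strata)
    if labels.shape != co.shape:
        raise StrategyError("strata must align with the category vectors")
    out = []
    for lab in dict.fromkeys(labels):  # preserve first-appearance order
        m = labels == lab
        old_med_neg = m & ~yy & (co == PtpCategory.MEDIUM)
        moved_neg = old_med_neg & (cn == PtpCategory.LOW)
        moved_pos = m & yy & (co == PtpCategory.MEDIUM) & (cn == PtpCategory.LOW)
        out.append(
            StratumImpact(
                stratum=str(lab),
                n_old_medium_neg=int(old_med_neg.sum()),
                n_moved_to_low_neg=int(moved_neg.sum()),
                n_moved_to_low_pos=int(moved_pos.sum()),
            )
        )
    return ImpactSummary(strata=tuple(out))


def events_among(group: Iterable[PatientRecord]) -> EventTally:
    """MACE composite among a record subset.

    Records without follow-up are excluded from the denominator and counted;
    the breakdown sums event kinds over MACE-positive individuals (late
    revascularizations only, per the composite definition).
    """
    records = list(group)
    if not records:
        raise StrategyError("empty group: event rate undefined")
    n_excluded = 0
    mace_count = 0
    n_followed = 0
    breakdown = {k.value: 0 for k in EventKind}
    for r in records:
        if r.followup_months is None or r.events is None:
            n_excluded += 1
            continue
        n_followed += 1
        is_mace, kinds = classify_mace(r)
        if is_mace:
            mace_count += 1
            for k in kinds:
                breakdown[k.value] += 1
    if n_followed == 0:
        raise StrategyError("no followed-up members: event rate undefined")
    return EventTally(
        n=len(records),
        n_followed=n_followed,
        n_excluded_no_followup=n_excluded,
        mace_count=mace_count,
        mace_rate=mace_count / n_followed,
        breakdown=breakdown,
    )
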