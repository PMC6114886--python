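"""Packaged reference fixtures: the published reclassification tables and
group-mean PTPs for the two low-risk-factor validation strata, so the NRI and
IDI arithmetic of the original comparison can be recomputed offline."""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .discrimination import idi_from_group_means
from .reclassification import NriResult, ReclassificationTable, nri_from_table

__all__ = [
    "published_reclassification_table",
    "published_group_means",
    "published_nri",
    "published_idi",
]

_STRATA = {"0 RF": "published_reclassification_0rf.json", "1 RF": "published_reclassification_1rf.json"}


def _read(name: str) -> dict:
    return json.loads(resources.files("ptpvalid.data").joinpath(name).read_text())


def published_reclassification_table(stratum: str) -> ReclassificationTable:
    """The published 3x3 new-by-old category counts for '0 RF' or '1 RF'."""
    try:
        d = _read(_STRATA[stratum])
    except KeyError:
        raise KeyError(f"unknown stratum {stratum!r}; use one of {sorted(_STRATA)}") from None
    return ReclassificationTable(
        counts_pos=np.asarray(d["counts_pos"], dtype=np.int64),
        counts_neg=np.asarray(d["counts_neg"], dtype=np.int64),
    )


def published_group_means(stratum: str) -> dict:
    d = _read("published_group_mean_ptp.json")
    if stratum not in d:
        raise KeyError(f"unknown stratum {stratum!r}")
    return d[stratum]


def published_nri(stratum: str) -> NriResult:
    """Categorical NRI recomputed from the published reclassification counts."""
    return nri_from_table(published_reclassification_table(stratum))


def published_idi(stratum: str) -> float:
    """IDI recomputed from the published group-mean PTPs."""
    gm = published_group_means(stratum)
    return idi_from_group_means(
        mean_pos_old=gm["old"]["mean_pos"],
        mean_neg_old=gm["old"]["mean_neg"],
        mean_pos_new=gm["new"]["mean_pos"],
        mean_neg_new=gm["new"]["mean_neg"],
    )
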