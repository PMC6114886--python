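"""Pipeline orchestration and report generation.

``validate_cohort`` runs the full model comparison on one stratum —
discrimination (AUC with DeLong comparison, IDI), categorical reclassification
(NRI with the full 3x3 tables), Hosmer-Lemeshow calibration, diagnostic
strategy impact, and MACE discrimination — and returns a nested dict that is
both the machine-readable report and the source for the text rendering.
``run_validation`` wires CSV/config inputs to per-stratum reports on disk.
``baseline_table`` reproduces group comparisons of baseline characteristics
(t or Mann-Whitney for continuous variables; chi-square, or Fisher's exact on
sparse 2x2 tables, for categorical ones).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .calibration import calibration_curve_data, hosmer_lemeshow, CalibrationError
from .cohort import CohortTable, ccs_category, read_cohort
from .discrimination import auc, delong_compare, idi
from .models import ModelSpec, batch_predict, load_model_spec
from .reclassification import (
    DEFAULT_CUTOFFS,
    assign_ptp_categories,
    build_reclassification_table,
    nri_from_table,
)
from .strategy import events_among, strategy_changes

__all__ = [
    "RunConfig",
    "BaselineComparison",
    "validate_cohort",
    "run_validation",
    "baseline_table",
    "render_text_report",
]


@dataclass(frozen=True)
class RunConfig:
    cohort_paths: tuple[str, ...]
    model_old_path: str
    model_new_path: str
    events_paths: tuple[Optional[str], ...] = ()
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS
    hl_groups: int = 10
    out_dir: str = "ptpvalid-report"
    seed: int = 0
    formats: tuple[str, ...] = ("json", "csv", "txt")
    stratum_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.cutoffs
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("cutoffs must be strictly increasing inside (0,1)")


@dataclass(frozen=True)
class BaselineComparison:
    variable: str
    test: str  # t, mann_whitney, chi_square, fisher, untestable
    statistic: Optional[float]
    p_value: Optional[float]


def _table_to_lists(m: np.ndarray) -> list[list[int]]:
    return [[int(v) for v in row] for row in m]


def validate_cohort(
    cohort: CohortTable,
    model_old: ModelSpec,
    model_new: ModelSpec,
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
    hl_groups: int = 10,
) -> dict:
    """Full comparison of two PTP models on one stratum."""
    frame = cohort.to_frame()
    y = np.asarray(cohort.outcomes(), dtype=bool)
    p_old = batch_predict(frame, model_old)
    p_new = batch_predict(frame, model_new)

    auc_old = auc(p_old, y)
    auc_new = auc(p_new, y)
    comparison = delong_compare(p_old, p_new, y)
    idi_res = idi(p_old, p_new, y)

    cats_old = assign_ptp_categories(p_old, cutoffs)
    cats_new = assign_ptp_categories(p_new, cutoffs)
    table = build_reclassification_table(cats_old, cats_new, y)
    nri_res = nri_from_table(table)

    calib = {}
    for label, p in (("old", p_old), ("new", p_new)):
        try:
            hl = hosmer_lemeshow(p, y, hl_groups)
            calib[label] = dict(
                chi2=hl.chi2,
                df=hl.df,
                p_value=hl.p_value,
                curve=hl.groups.to_frame().to_dict("records"),
            )
        except CalibrationError as e:
            calib[label] = dict(error=str(e))

    impact = strategy_changes(cats_old, cats_new, y)
    stratum_impact = impact.strata[0]
    moved_records = [
        r
        for r, yy, co, cn in zip(cohort.records, y, cats_old, cats_new)
        if not yy and co == 1 and cn == 0
    ]
    strategy_block: dict = dict(
        n_old_medium_neg=stratum_impact.n_old_medium_neg,
        n_moved_to_low_neg=stratum_impact.n_moved_to_low_neg,
        n_moved_to_low_pos=stratum_impact.n_moved_to_low_pos,
        fraction_moved=(
            stratum_impact.fraction_moved if stratum_impact.n_old_medium_neg else None
        ),
    )
    have_followup = any(r.followup_months is not None for r in cohort.records)
    if moved_records and have_followup:
        tally = events_among(moved_records)
        strategy_block["events_in_moved"] = dict(
            n=tally.n,
            n_followed=tally.n_followed,
            n_excluded_no_followup=tally.n_excluded_no_followup,
            mace_count=tally.mace_count,
            mace_rate=tally.mace_rate,
            breakdown=tally.breakdown,
        )

    mace_block: dict = {}
    if have_followup:
        followed = [r.followup_months is not None and r.events is not None for r in cohort.records]
        fmask = np.asarray(followed, dtype=bool)
        from .cohort import classify_mace

        y_mace = np.array(
            [classify_mace(r)[0] for r, f in zip(cohort.records, followed) if f], dtype=bool
        )
        mace_block["n_followed"] = int(fmask.sum())
        mace_block["n_excluded_no_followup"] = int((~fmask).sum())
        mace_block["mace_count"] = int(y_mace.sum())
        mace_block["mace_rate"] = float(y_mace.mean()) if len(y_mace) else None
        if y_mace.any() and (~y_mace).any():
            a_old = auc(p_old[fmask], y_mace)
            a_new = auc(p_new[fmask], y_mace)
            cmp_mace = delong_compare(p_old[fmask], p_new[fmask], y_mace)
            mace_block["auc_old"] = dict(auc=a_old.auc, ci95=list(a_old.ci95))
            mace_block["auc_new"] = dict(auc=a_new.auc, ci95=list(a_new.ci95))
            mace_block["delong_p"] = cmp_mace.p_value

    return dict(
        stratum=cohort.stratum_label,
        n=len(cohort),
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
        prevalence=float(y.mean()),
        models=dict(old=model_old.name, new=model_new.name),
        cutoffs=list(cutoffs),
        discrimination=dict(
            auc_old=dict(
                auc=auc_old.auc, variance=auc_old.variance, ci95=list(auc_old.ci95)
            ),
            auc_new=dict(
                auc=auc_new.auc, variance=auc_new.variance, ci95=list(auc_new.ci95)
            ),
            delong=dict(diff=comparison.diff, z=comparison.z, p_value=comparison.p_value),
            idi=dict(
                idi=idi_res.idi,
                z=idi_res.z,
                p_value=idi_res.p_value,
                mean_pos_old=idi_res.mean_pos_old,
                mean_pos_new=idi_res.mean_pos_new,
                mean_neg_old=idi_res.mean_neg_old,
                mean_neg_new=idi_res.mean_neg_new,
            ),
        ),
        reclassification=dict(
            counts_pos=_table_to_lists(table.counts_pos),
            counts_neg=_table_to_lists(table.counts_neg),
            nri=dict(
                up_pos=nri_res.up_pos,
                down_pos=nri_res.down_pos,
                up_neg=nri_res.up_neg,
                down_neg=nri_res.down_neg,
                nri_pos=nri_res.nri_pos,
                nri_neg=nri_res.nri_neg,
                nri_overall=nri_res.nri_overall,
                z=nri_res.z,
                p_value=nri_res.p_value,
            ),
        ),
        calibration=calib,
        strategy=strategy_block,
        mace=mace_block,
    )


def render_text_report(report: dict) -> str:
    """Human-readable block mirroring the validation summary."""
    d = report["discrimination"]
    r = report["reclassification"]["nri"]
    s = report["strategy"]
    lines = [
        f"Stratum {report['stratum'] or '(unlabelled)'}: n={report['n']}, "
        f"obstructive CAD {report['n_pos']} ({100 * report['prevalence']:.2f}%)",
        f"AUC {report['models']['old']}: {d['auc_old']['auc']:.3f} "
        f"({d['auc_old']['ci95'][0]:.3f} to {d['auc_old']['ci95'][1]:.3f})",
        f"AUC {report['models']['new']}: {d['auc_new']['auc']:.3f} "
        f"({d['auc_new']['ci95'][0]:.3f} to {d['auc_new']['ci95'][1]:.3f})",
        f"DeLong ΔAUC {d['delong']['diff']:.3f}, p = {d['delong']['p_value']:.4g}",
        f"IDI {100 * d['idi']['idi']:.2f}% (positives {100 * d['idi']['mean_pos_old']:.0f}%"
        f" → {100 * d['idi']['mean_pos_new']:.0f}%, negatives"
        f" {100 * d['idi']['mean_neg_old']:.0f}% → {100 * d['idi']['mean_neg_new']:.0f}%),"
        f" p = {d['idi']['p_value']:.4g}",
        f"NRI overall {100 * r['nri_overall']:.2f}% (positives {100 * r['nri_pos']:.2f}%, "
        f"negatives {100 * r['nri_neg']:.2f}%; up/down positives {r['up_pos']}/{r['down_pos']}, "
        f"negatives {r['up_neg']}/{r['down_neg']}), p = {r['p_value']:.4g}",
    ]
    for label in ("old", "new"):
        c = report["calibration"][label]
        if "chi2" in c:
            lines.append(
                f"H-L ({label}): chi2 = {c['chi2']:.2f}, df = {c['df']}, p = {c['p_value']:.4g}"
            )
        else:
            lines.append(f"H-L ({label}): {c['error']}")
    if s["n_old_medium_neg"]:
        lines.append(
            f"Strategy: {s['n_moved_to_low_neg']}/{s['n_old_medium_neg']} "
            f"({100 * s['fraction_moved']:.0f}%) negatives move from noninvasive testing "
            "to no further test"
        )
    ev = s.get("events_in_moved")
    if ev:
        lines.append(
            f"  among moved: {ev['mace_count']} MACE in {ev['n_followed']} followed "
            f"({100 * ev['mace_rate']:.1f}%; {ev['n_excluded_no_followup']} without follow-up)"
        )
    m = report.get("mace") or {}
    if "auc_old" in m:
        lines.append(
            f"MACE AUC: old {m['auc_old']['auc']:.3f}, new {m['auc_new']['auc']:.3f}, "
            f"DeLong p = {m['delong_p']:.4g} "
            f"({m['mace_count']} MACE / {m['n_followed']} followed; "
            f"{m['n_excluded_no_followup']} excluded without follow-up)"
        )
    return "\n".join(lines)


def _reclass_csv(report: dict) -> pd.DataFrame:
    rows = []
    cats = ["low", "medium", "high"]
    for outcome, key in (("positive", "counts_pos"), ("negative", "counts_neg")):
        m = report["reclassification"][key]
        for i, new_cat in enumerate(cats):
            for j, old_cat in enumerate(cats):
                rows.append(
                    dict(
                        stratum=report["stratum"],
                        outcome=outcome,
                        new_category=new_cat,
                        old_category=old_cat,
                        count=m[i][j],
                    )
                )
    return pd.DataFrame(rows)


def run_validation(rc: RunConfig) -> list[dict]:
    """Run the pipeline over the configured cohorts and write the report bundle."""
    out = Path(rc.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model_old = load_model_spec(rc.model_old_path)
    model_new = load_model_spec(rc.model_new_path)
    events = rc.events_paths or (None,) * len(rc.cohort_paths)
    labels = rc.stratum_labels or tuple(Path(p).stem for p in rc.cohort_paths)
    reports: list[dict] = []
    log_lines = [f"ptpvalid {__version__}", f"seed={rc.seed}"]
    for path, ev_path, label in zip(rc.cohort_paths, events, labels):
        cohort = read_cohort(path, events_path=ev_path, stratum_label=label)
        log_lines.append(f"cohort {label}: {len(cohort)} records from {path}")
        rep = validate_cohort(cohort, model_old, model_new, rc.cutoffs, rc.hl_groups)
        if rep.get("mace"):
            log_lines.append(
                f"cohort {label}: {rep['mace'].get('n_excluded_no_followup', 0)} "
                "records excluded from MACE analyses (no follow-up)"
            )
        reports.append(rep)
    if "json" in rc.formats:
        (out / "report.json").write_text(json.dumps(reports, indent=2))
    if "csv" in rc.formats:
        pd.concat([_reclass_csv(r) for r in reports]).to_csv(
            out / "reclassification.csv", index=False
        )
        cal_rows = []
        for r in reports:
            for label in ("old", "new"):
                c = r["calibration"][label]
                for g in c.get("curve", []):
                    cal_rows.append(dict(stratum=r["stratum"], model=label, **g))
        pd.DataFrame(cal_rows).to_csv(out / "calibration.csv", index=False)
    if "txt" in rc.formats:
        (out / "report.txt").write_text(
            "\n\n".join(render_text_report(r) for r in reports) + "\n"
        )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return reports


# ---------------------------------------------------------------------------
# Baseline characteristics

def _fisher_or_chi2(table: np.ndarray) -> tuple[str, float, float]:
    table = np.asarray(table, dtype=float)
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return "untestable", np.nan, np.nan
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if table.shape == (2, 2) and (expected < 5).any():
        stat, p = stats.fisher_exact(table)
        return "fisher", float(stat), float(p)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chi_square", float(chi2), float(p)


def baseline_table(
    cohort: CohortTable,
    y: Optional[Sequence[bool]] = None,
    continuous_tests: Optional[dict] = None,
) -> list[BaselineComparison]:
    """Compare baseline characteristics between outcome groups.

    ``continuous_tests`` maps variable name to 't' or 'mann_whitney'; the
    default uses t for age and Mann-Whitney for the skewed calcium score.
    """
    frame = cohort.to_frame()
    yy = np.asarray(cohort.outcomes() if y is None else y, dtype=bool)
    tests = {"age": "t", "ccs": "mann_whitney"}
    tests.update(continuous_tests or {})
    rows: list[BaselineComparison] = []

    for var in ("age", "ccs"):
        a = frame.loc[yy, var].to_numpy(float)
        b = frame.loc[~yy, var].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            rows.append(BaselineComparison(var, "untestable", None, None))
            continue
        if tests[var] == "t":
            res = stats.ttest_ind(a, b, equal_var=False)
            rows.append(BaselineComparison(var, "t", float(res.statistic), float(res.pvalue)))
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                BaselineComparison(var, "mann_whitney", float(res.statistic), float(res.pvalue))
            )

    binary_vars = [
        ("male", frame["sex"] == "male"),
        ("diabetes", frame["diabetes"].astype(bool)),
        ("hypertension", frame["hypertension"].astype(bool)),
        ("hyperlipidemia", frame["hyperlipidemia"].astype(bool)),
        ("smoking", frame["smoking"].astype(bool)),
        ("family_history", frame["family_history"].astype(bool)),
    ]
    for var, values in binary_vars:
        v = values.to_numpy(bool)
        if v.all() or (~v).all():
            rows.append(BaselineComparison(var, "untestable", None, None))
            continue
        table = np.array(
            [
                [int((v & yy).sum()), int((v & ~yy).sum())],
                [int((~v & yy).sum()), int((~v & ~yy).sum())],
            ]
        )
        test, stat, p = _fisher_or_chi2(table)
        rows.append(BaselineComparison(var, test, stat, p))

    for var, levels in (
        ("chest_pain", ["nonanginal", "atypical", "typical"]),
        ("ccs_category", None),
    ):
        if var == "chest_pain":
            cats = frame["chest_pain"].to_numpy()
        else:
            cats = np.array([ccs_category(v).value for v in frame["ccs"].to_numpy(float)])
            levels = ["zero", "gt0_le100", "gt100_le400", "gt400"]
        present = [lv for lv in levels if (cats == lv).any()]
        if len(present) < 2:
            rows.append(BaselineComparison(var, "untestable", None, None))
            continue
        table = np.array(
            [[int(((cats == lv) & m).sum()) for m in (yy, ~yy)] for lv in present]
        )
        test, stat, p = _fisher_or_chi2(table)
        rows.append(BaselineComparison(var, test, stat, p))
    return rows
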