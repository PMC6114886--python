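"""Patient data model, derived classifications, and CSV round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptpvalid.cohort import (
    CcsCategory,
    CohortTable,
    DataError,
    EventKind,
    FollowUpEvent,
    LATE_REVASC_MONTHS,
    PatientRecord,
    SchemaError,
    ccs_category,
    classify_mace,
    classify_obstructive,
    count_risk_factors,
    read_cohort,
    write_cohort,
)
from ptpvalid.synthetic import default_configs, generate_cohort

from conftest import make_record


class TestRiskFactorCount:
    @pytest.mark.parametrize(
        "flags, expected",
        [
            (dict(), 0),
            (dict(family_history=True), 0),  # family history never counts
            (dict(hypertension=True), 1),
            (dict(smoking=True, diabetes=True), 2),
            (dict(smoking=True, diabetes=True, hypertension=True, hyperlipidemia=True), 4),
        ],
    )
    def test_counts_only_the_four_traditional_factors(self, flags, expected):
        assert count_risk_factors(make_record(**flags)) == expected

    @given(
        rf=st.tuples(*(st.booleans(),) * 4),
        fh=st.booleans(),
        age=st.floats(18, 90),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_non_risk_factor_fields(self, rf, fh, age):
        smoking, diabetes, hypertension, hyperlipidemia = rf
        base = make_record(
            smoking=smoking,
            diabetes=diabetes,
            hypertension=hypertension,
            hyperlipidemia=hyperlipidemia,
        )
        varied = make_record(
            smoking=smoking,
            diabetes=diabetes,
            hypertension=hypertension,
            hyperlipidemia=hyperlipidemia,
            family_history=fh,
            age=age,
            sex="male",
            chest_pain="typical",
            ccs=321.0,
        )
        assert count_risk_factors(base) == count_risk_factors(varied) == sum(rf)


class TestObstructiveClassification:
    @pytest.mark.parametrize(
        "stenosis, nonassessable, expected",
        [
            (50.0, False, True),  # >=50% is inclusive
            (30.0, True, True),  # any non-assessable calcified segment
            (0.0, False, False),
            (49.9, False, False),
            (100.0, True, True),
        ],
    )
    def test_stenosis_rule(self, stenosis, nonassessable, expected):
        r = make_record(
            obstructive_cad=None,
            max_stenosis_pct=stenosis,
            nonassessable_calcified=nonassessable,
        )
        assert classify_obstructive(r) is expected

    def test_explicit_label_takes_precedence(self):
        r = make_record(
            obstructive_cad=False, max_stenosis_pct=90.0, nonassessable_calcified=True
        )
        assert classify_obstructive(r) is False

    @given(stenosis=st.floats(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_nonassessable_flag(self, stenosis):
        lo = make_record(
            obstructive_cad=None, max_stenosis_pct=stenosis, nonassessable_calcified=False
        )
        hi = make_record(
            obstructive_cad=None, max_stenosis_pct=stenosis, nonassessable_calcified=True
        )
        assert classify_obstructive(hi) >= classify_obstructive(lo)

    def test_missing_sources_is_an_error(self):
        with pytest.raises(DataError):
            make_record(obstructive_cad=None)


class TestCcsCategory:
    @pytest.mark.parametrize(
        "ccs, expected",
        [
            (0.0, CcsCategory.ZERO),
            (0.5, CcsCategory.GT0_LE100),
            (100.0, CcsCategory.GT0_LE100),
            (100.1, CcsCategory.GT100_LE400),
            (400.0, CcsCategory.GT100_LE400),
            (401.0, CcsCategory.GT400),
        ],
    )
    def test_bin_boundaries(self, ccs, expected):
        assert ccs_category(ccs) is expected

    def test_negative_is_an_error(self):
        with pytest.raises(DataError):
            ccs_category(-1.0)

    @given(st.floats(0, 1e6, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_partitions_nonnegative_reals(self, ccs):
        assert ccs_category(ccs) in list(CcsCategory)


class TestMace:
    def _with_events(self, events, followup=24.0):
        return make_record(followup_months=followup, events=events)

    def test_late_revascularization_counts(self):
        r = self._with_events([FollowUpEvent(EventKind.REVASCULARIZATION, 3.0)])
        is_mace, kinds = classify_mace(r)
        assert is_mace and kinds == [EventKind.REVASCULARIZATION]

    def test_early_revascularization_does_not_count(self):
        r = self._with_events([FollowUpEvent(EventKind.REVASCULARIZATION, 1.0)])
        is_mace, kinds = classify_mace(r)
        assert not is_mace and kinds == []

    def test_threshold_is_sixty_days(self):
        just_under = self._with_events(
            [FollowUpEvent(EventKind.REVASCULARIZATION, LATE_REVASC_MONTHS)]
        )
        just_over = self._with_events(
            [FollowUpEvent(EventKind.REVASCULARIZATION, LATE_REVASC_MONTHS + 1e-6)]
        )
        assert not classify_mace(just_under)[0]
        assert classify_mace(just_over)[0]

    @pytest.mark.parametrize(
        "kind", [EventKind.CARDIAC_DEATH, EventKind.NONFATAL_MI, EventKind.UNSTABLE_ANGINA_HOSP]
    )
    def test_hard_events_count_at_any_time(self, kind):
        assert classify_mace(self._with_events([FollowUpEvent(kind, 0.5)]))[0]

    def test_empty_events_is_not_mace(self):
        assert not classify_mace(self._with_events([]))[0]

    def test_absent_events_is_an_error(self):
        with pytest.raises(DataError):
            classify_mace(make_record())

    def test_event_after_followup_rejected(self):
        with pytest.raises(DataError):
            make_record(
                followup_months=2.0,
                events=[FollowUpEvent(EventKind.NONFATAL_MI, 5.0)],
            )


class TestCsvIo:
    def test_well_formed_csv(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "id,age,sex,chest_pain,diabetes,hypertension,hyperlipidemia,smoking,"
            "family_history,ccs,obstructive_cad\n"
            "a,55,male,typical,1,0,no,Yes,FALSE,12.5,true\n"
            "b,60,female,atypical,0,0,0,0,0,0,0\n"
            "c,70,male,nonanginal,0,1,0,0,1,401,1\n"
        )
        cohort = read_cohort(p)
        assert len(cohort) == 3
        a = cohort.records[0]
        assert a.diabetes and a.smoking and not a.hyperlipidemia and a.obstructive_cad
        assert cohort.records[2].ccs == 401.0

    def test_missing_mandatory_column_names_it(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("id,sex,chest_pain,diabetes,hypertension,hyperlipidemia,smoking,family_history,ccs\n")
        with pytest.raises(SchemaError, match="age"):
            read_cohort(p)

    def test_unparseable_cell_reports_row(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "id,age,sex,chest_pain,diabetes,hypertension,hyperlipidemia,smoking,"
            "family_history,ccs,obstructive_cad\n"
            "a,55,male,typical,maybe,0,0,0,0,1,0\n"
        )
        with pytest.raises(DataError, match="row 2"):
            read_cohort(p)

    def test_column_remapping(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "pid,age,sex,chest_pain,diabetes,hypertension,hyperlipidemia,smoking,"
            "family_history,agatston,obstructive_cad\n"
            "a,55,male,typical,0,0,0,0,0,7,1\n"
        )
        cohort = read_cohort(p, schema={"id": "pid", "ccs": "agatston"})
        assert cohort.records[0].id == "a" and cohort.records[0].ccs == 7.0

    def test_round_trip_preserves_every_field(self, tmp_path):
        cfg0, _ = default_configs(seed=11)
        from dataclasses import replace

        cohort = generate_cohort(replace(cfg0, n=100))
        cp, ep = tmp_path / "c.csv", tmp_path / "e.csv"
        write_cohort(cohort, cp, ep)
        back = read_cohort(cp, events_path=ep, stratum_label=cohort.stratum_label)
        assert len(back) == len(cohort)
        for orig, rt in zip(cohort.records, back.records):
            assert orig == rt

    def test_duplicate_ids_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            CohortTable([make_record(id="x"), make_record(id="x")])
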