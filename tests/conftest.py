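import numpy as np
import pytest

from ptpvalid.cohort import CohortTable, FollowUpEvent, PatientRecord


def make_record(
    id="p1",
    age=55.0,
    sex="female",
    chest_pain="nonanginal",
    diabetes=False,
    hypertension=False,
    hyperlipidemia=False,
    smoking=False,
    family_history=False,
    ccs=0.0,
    **kw,
):
    kw.setdefault("obstructive_cad", False)
    return PatientRecord(
        id=id,
        age=age,
        sex=sex,
        chest_pain=chest_pain,
        diabetes=diabetes,
        hypertension=hypertension,
        hyperlipidemia=hyperlipidemia,
        smoking=smoking,
        family_history=family_history,
        ccs=ccs,
        **kw,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


def random_cohort(rng, n, label="test"):
    """Covariate-random cohort with Bernoulli outcome, for oracle tests."""
    records = []
    for i in range(n):
        records.append(
            make_record(
                id=f"{label}-{i}",
                age=float(rng.uniform(25, 85)),
                sex="male" if rng.random() < 0.5 else "female",
                chest_pain=["nonanginal", "atypical", "typical"][rng.integers(3)],
                diabetes=bool(rng.random() < 0.2),
                hypertension=bool(rng.random() < 0.3),
                hyperlipidemia=bool(rng.random() < 0.25),
                smoking=bool(rng.random() < 0.25),
                family_history=bool(rng.random() < 0.2),
                ccs=float(rng.choice([0.0, rng.lognormal(4, 1.3)])),
                obstructive_cad=bool(rng.random() < 0.3),
            )
        )
    return CohortTable(records, stratum_label=label)


@pytest.fixture
def random_cohort_factory():
    return random_cohort
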