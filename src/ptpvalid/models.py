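"""Config-driven pretest-probability (PTP) scoring engine.

A PTP model is a logistic linear predictor over clinical covariates:

    eta = b0 + sum_j b_j * x_j,    PTP = 1 / (1 + exp(-eta))

Two model shapes are supported, mirroring the published CONFIRM clinical
score (age, sex, chest-pain type, diabetes, hypertension, family history,
smoking) and the Genders extended model, GEM (age, sex, chest-pain type,
dyslipidaemia, diabetes, hypertension, smoking and the coronary calcium
score).  Coefficient values are pure configuration: the published numbers
belong to the original model papers and entering them is a config exercise,
not a code change.  The package ships documented example coefficient sets
with the correct covariate structure, used by tests and the synthetic cohort
generator.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import ChestPain, CohortTable, PatientRecord, Sex, ccs_category, CcsCategory

__all__ = [
    "CovariateTerm",
    "ModelSpec",
    "ScoringError",
    "ConfigError",
    "linear_predictor",
    "predict_ptp",
    "batch_predict",
    "load_model_spec",
    "example_confirm_style_spec",
    "example_gem_style_spec",
]

# Covariates a term may reference.  ccs_transform applies log_base(ccs + shift);
# ccs_category_indicator is a dummy for one CCS stratum (reference: zero).
SIMPLE_COVARIATES = {
    "age_linear",
    "sex_male",
    "chest_pain_typical",
    "chest_pain_atypical",
    "diabetes",
    "hypertension",
    "hyperlipidemia",
    "smoking",
    "family_history",
}
CCS_COVARIATES = {"ccs_transform", "ccs_category_indicator"}
KNOWN_COVARIATES = SIMPLE_COVARIATES | CCS_COVARIATES

CONFIRM_COVARIATES = {
    "age_linear",
    "sex_male",
    "chest_pain_typical",
    "chest_pain_atypical",
    "diabetes",
    "hypertension",
    "family_history",
    "smoking",
}
GEM_COVARIATES = {
    "age_linear",
    "sex_male",
    "chest_pain_typical",
    "chest_pain_atypical",
    "hyperlipidemia",
    "diabetes",
    "hypertension",
    "smoking",
}  # plus exactly one CCS term family


class ScoringError(ValueError):
    """A record lacks a covariate the model requires."""


class ConfigError(ValueError):
    """A model config file is malformed."""


@dataclass(frozen=True)
class CovariateTerm:
    covariate: str
    coefficient: float
    transform_params: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.covariate not in KNOWN_COVARIATES:
            raise ConfigError(f"unknown covariate {self.covariate!r}")
        if self.covariate == "ccs_category_indicator":
            level = (self.transform_params or {}).get("level")
            valid = {c.value for c in CcsCategory} - {CcsCategory.ZERO.value}
            if level not in valid:
                raise ConfigError(
                    f"ccs_category_indicator needs transform_params.level in {sorted(valid)}"
                )


@dataclass(frozen=True)
class ModelSpec:
    """A PTP model: named coefficient set over a logistic link."""

    name: str
    intercept: float
    terms: tuple[CovariateTerm, ...]
    link: str = "logistic"
    ptp_scale: str = "probability"

    def __post_init__(self) -> None:
        if self.link != "logistic":
            raise ConfigError(f"unsupported link {self.link!r}")
        if self.ptp_scale != "probability":
            raise ConfigError(f"unsupported ptp_scale {self.ptp_scale!r}")
        families = [t.covariate for t in self.terms if t.covariate in CCS_COVARIATES]
        if "ccs_transform" in families and "ccs_category_indicator" in families:
            raise ConfigError("a model may use only one CCS term family")
        if sum(t.covariate == "ccs_transform" for t in self.terms) > 1:
            raise ConfigError("duplicate ccs_transform terms")

    @property
    def uses_ccs(self) -> bool:
        return any(t.covariate in CCS_COVARIATES for t in self.terms)

    def with_intercept(self, intercept: float) -> "ModelSpec":
        return replace(self, intercept=intercept)

    def scaled(self, factor: float, name: Optional[str] = None) -> "ModelSpec":
        """Copy with every slope coefficient multiplied by ``factor``."""
        terms = tuple(replace(t, coefficient=t.coefficient * factor) for t in self.terms)
        return replace(self, terms=terms, name=name or f"{self.name} (x{factor:g})")


def _ccs_transform_value(ccs: float, params: Optional[dict]) -> float:
    params = params or {}
    kind = params.get("kind", "log")
    if kind != "log":
        raise ConfigError(f"unknown ccs transform kind {kind!r}")
    shift = float(params.get("shift", 1.0))
    base = params.get("base", "e")
    x = math.log(ccs + shift)
    if base != "e":
        x /= math.log(float(base))
    return x


def _covariate_value(r: PatientRecord, term: CovariateTerm) -> float:
    c = term.covariate
    if c == "age_linear":
        return float(r.age)
    if c == "sex_male":
        return 1.0 if r.sex is Sex.MALE else 0.0
    if c == "chest_pain_typical":
        return 1.0 if r.chest_pain is ChestPain.TYPICAL else 0.0
    if c == "chest_pain_atypical":
        return 1.0 if r.chest_pain is ChestPain.ATYPICAL else 0.0
    if c in ("diabetes", "hypertension", "hyperlipidemia", "smoking", "family_history"):
        v = getattr(r, c)
        if v is None:
            raise ScoringError(f"record {r.id!r}: covariate {c} absent")
        return float(bool(v))
    if c == "ccs_transform":
        if r.ccs is None:
            raise ScoringError(f"record {r.id!r}: covariate ccs absent")
        return _ccs_transform_value(r.ccs, term.transform_params)
    if c == "ccs_category_indicator":
        level = term.transform_params["level"]
        return 1.0 if ccs_category(r.ccs).value == level else 0.0
    raise ScoringError(f"unknown covariate {c!r}")  # pragma: no cover


def linear_predictor(r: PatientRecord, m: ModelSpec) -> float:
    """eta = intercept + sum of coefficient * encoded covariate."""
    eta = m.intercept
    for term in m.terms:
        eta += term.coefficient * _covariate_value(r, term)
    return eta


def predict_ptp(r: PatientRecord, m: ModelSpec) -> float:
    """Pretest probability 1/(1+exp(-eta)); strictly inside (0, 1)."""
    eta = linear_predictor(r, m)
    if eta >= 0:
        p = 1.0 / (1.0 + math.exp(-eta))
    else:
        e = math.exp(eta)
        p = e / (1.0 + e)
    # guard against underflow to exactly 0/1 at extreme eta
    tiny = 5e-324
    return min(max(p, tiny), 1.0 - 1e-16)


def _frame_design(df: pd.DataFrame, m: ModelSpec) -> np.ndarray:
    """Vectorized linear predictor over a cohort frame."""
    eta = np.full(len(df), float(m.intercept))
    for term in m.terms:
        c = term.covariate
        if c == "age_linear":
            x = df["age"].to_numpy(float)
        elif c == "sex_male":
            x = (df["sex"] == "male").to_numpy(float)
        elif c == "chest_pain_typical":
            x = (df["chest_pain"] == "typical").to_numpy(float)
        elif c == "chest_pain_atypical":
            x = (df["chest_pain"] == "atypical").to_numpy(float)
        elif c in ("diabetes", "hypertension", "hyperlipidemia", "smoking", "family_history"):
            col = df[c]
            if col.isna().any():
                bad = df.loc[col.isna(), "id"].tolist()[:5]
                raise ScoringError(f"covariate {c} absent for records {bad}")
            x = col.to_numpy(float)
        elif c == "ccs_transform":
            params = term.transform_params or {}
            shift = float(params.get("shift", 1.0))
            base = params.get("base", "e")
            x = np.log(df["ccs"].to_numpy(float) + shift)
            if base != "e":
                x /= math.log(float(base))
        elif c == "ccs_category_indicator":
            level = term.transform_params["level"]
            cats = np.array([ccs_category(v).value for v in df["ccs"].to_numpy(float)])
            x = (cats == level).astype(float)
        else:  # pragma: no cover
            raise ScoringError(f"unknown covariate {c!r}")
        eta += term.coefficient * x
    return eta


def batch_predict(cohort: CohortTable | pd.DataFrame, m: ModelSpec) -> np.ndarray:
    """PTP for every record, aligned to record order."""
    df = cohort.to_frame() if isinstance(cohort, CohortTable) else cohort
    if len(df) == 0:
        return np.empty(0)
    eta = _frame_design(df, m)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-eta))
    return np.clip(p, 5e-324, 1.0 - 1e-16)


# ---------------------------------------------------------------------------
# Config I/O

def _spec_from_dict(d: dict) -> ModelSpec:
    try:
        terms = tuple(
            CovariateTerm(
                covariate=t["covariate"],
                coefficient=float(t["coefficient"]),
                transform_params=t.get("transform_params"),
            )
            for t in d["terms"]
        )
        spec = ModelSpec(
            name=str(d["name"]),
            intercept=float(d["intercept"]),
            terms=terms,
            link=d.get("link", "logistic"),
            ptp_scale=d.get("ptp_scale", "probability"),
        )
    except (KeyError, TypeError) as e:
        raise ConfigError(f"malformed model config: {e}") from e
    _warn_on_shape_mismatch(spec, d.get("shape"))
    return spec


def _warn_on_shape_mismatch(spec: ModelSpec, shape: Optional[str]) -> None:
    """Warn when a config declaring a known model shape deviates from its
    published covariate list (CONFIRM: family history, no lipids or CCS;
    GEM: dyslipidaemia and CCS, no family history)."""
    if shape is None:
        return
    covs = {t.covariate for t in spec.terms}
    if shape == "confirm":
        expected, ccs_ok = CONFIRM_COVARIATES, False
    elif shape == "gem":
        expected, ccs_ok = GEM_COVARIATES, True
    else:
        raise ConfigError(f"unknown model shape {shape!r}")
    simple = covs & SIMPLE_COVARIATES
    if simple != expected:
        warnings.warn(
            f"model {spec.name!r} declares shape={shape!r} but covariates "
            f"{sorted(simple ^ expected)} differ from the published list",
            stacklevel=3,
        )
    if ccs_ok and not spec.uses_ccs:
        warnings.warn(f"model {spec.name!r}: GEM shape without a CCS term", stacklevel=3)
    if not ccs_ok and spec.uses_ccs:
        warnings.warn(f"model {spec.name!r}: CONFIRM shape with a CCS term", stacklevel=3)


def load_model_spec(path: str | Path) -> ModelSpec:
    """Load a model spec from JSON or YAML config."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        import yaml

        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return _spec_from_dict(d)


def _load_packaged(name: str) -> ModelSpec:
    text = resources.files("ptpvalid.data").joinpath(name).read_text()
    return _spec_from_dict(json.loads(text))


def example_confirm_style_spec() -> ModelSpec:
    """Documented example coefficient set with the CONFIRM covariate structure."""
    return _load_packaged("confirm_style_example.json")


def example_gem_style_spec() -> ModelSpec:
    """Documented example coefficient set with the GEM covariate structure."""
    return _load_packaged("gem_style_example.json")
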