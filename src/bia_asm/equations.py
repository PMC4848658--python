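"""Registry of the five published BIA prediction equations for ASM.

Each equation is a linear combination of the impedance index (height in
cm)^2 / R, weight, a numeric sex term (men = 1, women = 0) and, for some
equations, age and reactance Xc.  Coefficients are transcribed literally
from the source publications' printed forms; ``registry_self_test`` compares
the live registry against that transcription.

Conventions fixed here (see docs/methods.md for the reasoning):

* the impedance/resistance index is (height in cm)^2 / R in cm^2/Ohm — the
  direction that reproduces plausible muscle masses; the inverted reading
  R/Ht^2 that appears in one published footnote is a known typographic slip;
* the Yoshida equations use an undefined "impedance index"; the default here
  is Ht^2/Z with Z = sqrt(R^2 + Xc^2) at 50 kHz, switchable to Ht^2/R;
* the Kim equation was developed on a multi-frequency instrument; applying
  it to single-frequency 50 kHz data (as done here) carries a provenance
  warning on the spec.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ValidationError
from .records import IndexKind, Sex, SubjectRecord, sex_code

#: bumped whenever a stored coefficient changes; emitted in report provenance
REGISTRY_VERSION = "table1-v1"

EQUATION_NAMES: Tuple[str, ...] = ("sergi", "kyle", "peniche", "kim", "yoshida")

#: coefficient names understood by the evaluator
_TERMS = ("intercept", "index", "weight", "sex", "age", "reactance")


@dataclass(frozen=True)
class EquationSpec:
    """Metadata and coefficients for one ASM prediction equation.

    ``coefficients`` maps term name -> value for single-set equations; the
    Yoshida equation instead carries one set per sex in ``coefficients_by_sex``.
    """

    name: str
    index_kind: IndexKind
    source_population: str
    instrument_class: str  # "single_frequency" | "multi_frequency"
    required_inputs: Tuple[str, ...]
    coefficients: Optional[Mapping[str, float]] = None
    coefficients_by_sex: Optional[Mapping[Sex, Mapping[str, float]]] = None
    warning: Optional[str] = None

    def coefficient_set(self, sex: Sex) -> Mapping[str, float]:
        if self.coefficients_by_sex is not None:
            return self.coefficients_by_sex[Sex(sex)]
        assert self.coefficients is not None
        return self.coefficients


_KIM_WARNING = (
    "the Kim equation was developed on a multi-frequency instrument; "
    "applying it to single-frequency 50 kHz measurements is an "
    "out-of-provenance use"
)

REGISTRY: Dict[str, EquationSpec] = {
    "sergi": EquationSpec(
        name="sergi",
        index_kind=IndexKind.HT2_OVER_R,
        source_population="Caucasian (Italy)",
        instrument_class="single_frequency",
        required_inputs=("sex", "height", "weight", "resistance", "reactance"),
        coefficients={
            "intercept": -3.964,
            "index": 0.227,
            "weight": 0.095,
            "sex": 1.384,
            "reactance": 0.064,
        },
    ),
    "kyle": EquationSpec(
        name="kyle",
        index_kind=IndexKind.HT2_OVER_R,
        source_population="Caucasian (Switzerland)",
        instrument_class="single_frequency",
        required_inputs=("sex", "age", "height", "weight", "resistance", "reactance"),
        coefficients={
            "intercept": -4.211,
            "index": 0.267,
            "weight": 0.095,
            "sex": 1.909,
            "age": -0.012,
            "reactance": 0.058,
        },
    ),
    "peniche": EquationSpec(
        name="peniche",
        index_kind=IndexKind.HT2_OVER_R,
        source_population="Mexican",
        instrument_class="single_frequency",
        required_inputs=("sex", "height", "weight", "resistance"),
        coefficients={
            "intercept": -0.05376,
            "index": 0.2394,
            "sex": 2.708,
            "weight": 0.065,
        },
    ),
    "kim": EquationSpec(
        name="kim",
        index_kind=IndexKind.HT2_OVER_R,
        source_population="Korean",
        instrument_class="multi_frequency",
        required_inputs=("sex", "age", "height", "weight", "resistance"),
        coefficients={
            "intercept": 5.663,
            "index": 0.104,
            "age": -0.050,
            "sex": 2.954,
            "weight": 0.055,
        },
        warning=_KIM_WARNING,
    ),
    "yoshida": EquationSpec(
        name="yoshida",
        index_kind=IndexKind.HT2_OVER_Z,
        source_population="Japanese",
        instrument_class="multi_frequency",
        required_inputs=("sex", "height", "weight", "resistance", "reactance"),
        coefficients_by_sex={
            Sex.MALE: {"intercept": -0.019, "index": 0.197, "weight": 0.179},
            Sex.FEMALE: {"intercept": 0.881, "index": 0.221, "weight": 0.117},
        },
    ),
}

# Literal transcription of the published coefficient table, kept deliberately
# separate from REGISTRY so a self-test can diff one against the other.
_PUBLISHED_TABLE = {
    "sergi": {"intercept": -3.964, "index": 0.227, "weight": 0.095, "sex": 1.384, "reactance": 0.064},
    "kyle": {"intercept": -4.211, "index": 0.267, "weight": 0.095, "sex": 1.909, "age": -0.012, "reactance": 0.058},
    "peniche": {"intercept": -0.05376, "index": 0.2394, "sex": 2.708, "weight": 0.065},
    "kim": {"intercept": 5.663, "index": 0.104, "age": -0.050, "sex": 2.954, "weight": 0.055},
    ("yoshida", "male"): {"intercept": -0.019, "index": 0.197, "weight": 0.179},
    ("yoshida", "female"): {"intercept": 0.881, "index": 0.221, "weight": 0.117},
}


def registry_self_test() -> None:
    """Raise if any live registry coefficient deviates from the transcription."""
    for key, published in _PUBLISHED_TABLE.items():
        if isinstance(key, tuple):
            name, sex = key
            stored = dict(REGISTRY[name].coefficients_by_sex[Sex(sex)])
        else:
            stored = dict(REGISTRY[key].coefficients)
        if stored != dict(published):
            raise AssertionError(f"registry coefficients for {key!r} deviate: {stored} != {published}")


def get_equation(name: str) -> EquationSpec:
    try:
        return REGISTRY[name]
    except KeyError:
        raise ValidationError(
            f"unknown equation {name!r}; valid names: {', '.join(EQUATION_NAMES)}"
        ) from None


def resolve_equations(names) -> Tuple[EquationSpec, ...]:
    """Resolve ``"all"``, a comma string or a sequence of names to specs."""
    if names is None or names == "all":
        return tuple(REGISTRY[n] for n in EQUATION_NAMES)
    if isinstance(names, str):
        names = [n.strip() for n in names.split(",") if n.strip()]
    return tuple(get_equation(n) for n in names)


def _evaluate_arrays(
    spec: EquationSpec,
    sex_num: np.ndarray,
    age: np.ndarray,
    height_m: np.ndarray,
    weight: np.ndarray,
    resistance: np.ndarray,
    reactance: np.ndarray,
    yoshida_index: str = "z",
) -> np.ndarray:
    """Vectorised evaluation of one equation on parallel arrays."""
    kind = spec.index_kind
    if spec.name == "yoshida" and yoshida_index == "r":
        kind = IndexKind.HT2_OVER_R
    ht_cm2 = (100.0 * height_m) ** 2
    if kind is IndexKind.HT2_OVER_Z:
        denom = np.hypot(resistance, reactance)
    else:
        denom = resistance
    index = ht_cm2 / denom

    def combine(c: Mapping[str, float]) -> np.ndarray:
        out = np.full_like(index, c.get("intercept", 0.0))
        out += c.get("index", 0.0) * index
        out += c.get("weight", 0.0) * weight
        out += c.get("sex", 0.0) * sex_num
        out += c.get("age", 0.0) * age
        out += c.get("reactance", 0.0) * reactance
        return out

    if spec.coefficients_by_sex is not None:
        male = combine(spec.coefficients_by_sex[Sex.MALE])
        female = combine(spec.coefficients_by_sex[Sex.FEMALE])
        return np.where(sex_num == 1, male, female)
    return combine(spec.coefficients)


def predict_asm(
    record: SubjectRecord,
    equation: EquationSpec | str,
    yoshida_index: str = "z",
) -> float:
    """Predicted appendicular skeletal muscle mass (kg) for one subject."""
    spec = get_equation(equation) if isinstance(equation, str) else equation
    for field_name in spec.required_inputs:
        if getattr(record, field_name, None) is None:
            raise ValidationError(
                f"record {record.id!r} is missing required input "
                f"{field_name!r} for equation {spec.name!r}"
            )
    return float(
        _evaluate_arrays(
            spec,
            np.asarray(record.sex_code, dtype=float),
            np.asarray(record.age, dtype=float),
            np.asarray(record.height, dtype=float),
            np.asarray(record.weight, dtype=float),
            np.asarray(record.resistance, dtype=float),
            np.asarray(record.reactance, dtype=float),
            yoshida_index,
        )
    )


def predict_records(records: Sequence[SubjectRecord], equation, yoshida_index: str = "z") -> np.ndarray:
    spec = get_equation(equation) if isinstance(equation, str) else equation
    return _evaluate_arrays(
        spec,
        np.array([r.sex_code for r in records], dtype=float),
        np.array([r.age for r in records], dtype=float),
        np.array([r.height for r in records], dtype=float),
        np.array([r.weight for r in records], dtype=float),
        np.array([r.resistance for r in records], dtype=float),
        np.array([r.reactance for r in records], dtype=float),
        yoshida_index,
    )


_COLUMN_MAP = {
    "sex": "sex",
    "age": "age",
    "height": "height_m",
    "weight": "weight_kg",
    "resistance": "resistance_ohm",
    "reactance": "reactance_ohm",
}


class ASMPredictor(BaseEstimator):
    """Scikit-learn style predictor evaluating one published ASM equation.

    The coefficients are fixed by the literature, so ``fit`` only validates
    the input schema and records fitted metadata; ``predict`` evaluates the
    equation row-wise on a DataFrame with columns ``sex``, ``age``,
    ``height_m``, ``weight_kg``, ``resistance_ohm``, ``reactance_ohm``.

    Parameters
    ----------
    equation : str, default "sergi"
        One of ``sergi``, ``kyle``, ``peniche``, ``kim``, ``yoshida``.
    yoshida_index : {"z", "r"}, default "z"
        Denominator convention for the Yoshida impedance index.
    """

    def __init__(self, equation: str = "sergi", yoshida_index: str = "z"):
        self.equation = equation
        self.yoshida_index = yoshida_index

    def _validate_frame(self, X: pd.DataFrame, spec: EquationSpec) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise ValidationError("X must be a pandas DataFrame of subject rows")
        needed = [_COLUMN_MAP[f] for f in spec.required_inputs if f in _COLUMN_MAP]
        missing = [c for c in needed if c not in X.columns]
        if missing:
            raise ValidationError(
                f"equation {spec.name!r} requires missing column(s): {', '.join(missing)}"
            )
        return X

    def fit(self, X: pd.DataFrame, y=None) -> "ASMPredictor":
        if self.yoshida_index not in ("z", "r"):
            raise ValidationError(f"yoshida_index must be 'z' or 'r', got {self.yoshida_index!r}")
        spec = get_equation(self.equation)
        X = self._validate_frame(X, spec)
        self.equation_spec_ = spec
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "equation_spec_"):
            raise ValidationError("this ASMPredictor instance is not fitted yet; call fit first")
        spec = self.equation_spec_
        X = self._validate_frame(X, spec)
        sex_num = np.array([sex_code(s) for s in X["sex"]], dtype=float)
        age = X["age"].to_numpy(float) if "age" in X.columns else np.zeros(len(X))
        return _evaluate_arrays(
            spec,
            sex_num,
            age,
            X["height_m"].to_numpy(float),
            X["weight_kg"].to_numpy(float),
            X["resistance_ohm"].to_numpy(float),
            X["reactance_ohm"].to_numpy(float),
            self.yoshida_index,
        )
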