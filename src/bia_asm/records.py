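"""Subject records and derived anthropometric / impedance quantities.

A :class:`SubjectRecord` holds one participant's sex, age, anthropometry and
single-frequency (50 kHz) impedance measurements, with hard physiological
sanity ranges enforced at construction.  Derived quantities — BMI and its
band, the impedance magnitude Z = sqrt(R^2 + Xc^2), and the impedance index
Ht^2/R (or Ht^2/Z) in cm^2/Ohm — live here so that the prediction-equation
registry and the cohort generator share one definition.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

from .errors import ValidationError


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class BMIBand(str, enum.Enum):
    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE = "obese"


class IndexKind(str, enum.Enum):
    """Denominator convention of the impedance index Ht^2/denominator."""

    HT2_OVER_R = "ht2_over_R"
    HT2_OVER_Z = "ht2_over_Z"
    NONE = "none"


#: accepted spellings at parse time, normalised to the enumeration
_SEX_ALIASES = {
    "male": Sex.MALE,
    "m": Sex.MALE,
    "1": Sex.MALE,
    "female": Sex.FEMALE,
    "f": Sex.FEMALE,
    "0": Sex.FEMALE,
}

#: hard validity ranges (open intervals unless noted)
HEIGHT_RANGE_M = (0.5, 2.5)
WEIGHT_RANGE_KG = (20.0, 300.0)
RESISTANCE_RANGE_OHM = (100.0, 1500.0)
REACTANCE_RANGE_OHM = (0.0, 200.0)  # lower bound inclusive


def parse_sex(value) -> Sex:
    """Normalise a sex label (``male``/``female``/``M``/``F``/``1``/``0``)."""
    if isinstance(value, Sex):
        return value
    key = str(value).strip().lower()
    try:
        return _SEX_ALIASES[key]
    except KeyError:
        raise ValidationError(
            f"unknown sex label {value!r}; expected one of male, female, M, F, 1, 0"
        ) from None


def sex_code(sex) -> int:
    """Numeric sex coding used by every prediction equation: men = 1, women = 0."""
    return 1 if parse_sex(sex) is Sex.MALE else 0


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index: weight (kg) divided by height (m) squared."""
    if not (weight_kg > 0 and math.isfinite(weight_kg)):
        raise ValidationError(f"weight must be positive and finite, got {weight_kg}")
    if not (height_m > 0 and math.isfinite(height_m)):
        raise ValidationError(f"height must be positive and finite, got {height_m}")
    return weight_kg / height_m**2


def bmi_band(bmi: float) -> BMIBand:
    """Band boundaries: <18.5, [18.5, 25), [25, 30), >=30 kg/m^2.

    Boundary values are assigned to the higher band; 18.5 is normal.
    """
    if bmi < 18.5:
        return BMIBand.UNDERWEIGHT
    if bmi < 25.0:
        return BMIBand.NORMAL
    if bmi < 30.0:
        return BMIBand.OVERWEIGHT
    return BMIBand.OBESE


def impedance_z(resistance_ohm: float, reactance_ohm: float) -> float:
    """Impedance magnitude Z = sqrt(R^2 + Xc^2), in Ohm."""
    return math.hypot(resistance_ohm, reactance_ohm)


def impedance_index(
    height_m: float,
    resistance_ohm: float,
    kind: IndexKind | str = IndexKind.HT2_OVER_R,
    reactance_ohm: float = 0.0,
) -> float:
    """Impedance index (height in cm)^2 / denominator, in cm^2/Ohm.

    The API takes height in metres; the conversion to centimetres happens
    here and nowhere else.  ``kind`` selects the denominator: the resistance
    R at 50 kHz, or the impedance magnitude Z = sqrt(R^2 + Xc^2).
    """
    kind = IndexKind(kind)
    if not height_m > 0:
        raise ValidationError(f"height must be positive, got {height_m}")
    if kind is IndexKind.HT2_OVER_Z:
        denom = impedance_z(resistance_ohm, reactance_ohm)
    else:
        denom = resistance_ohm
    if not denom > 0:
        raise ValidationError(f"impedance-index denominator must be positive, got {denom}")
    return (100.0 * height_m) ** 2 / denom


def _check_range(name: str, value: float, lo: float, hi: float, lo_inclusive: bool = False):
    ok_lo = value >= lo if lo_inclusive else value > lo
    if not (math.isfinite(value) and ok_lo and value < hi):
        bracket = "[" if lo_inclusive else "("
        raise ValidationError(f"{name}={value} outside valid range {bracket}{lo}, {hi})")


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: sex, age, anthropometry and 50 kHz impedance.

    Heights are metres, weight kg, resistance/reactance Ohm; the optional
    ``reference_asm`` is the criterion appendicular skeletal muscle mass in
    kg (DXA-derived when working with real data).
    """

    id: str
    sex: Sex
    age: float
    height: float
    weight: float
    resistance: float
    reactance: float
    reference_asm: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "sex", parse_sex(self.sex))
        if not (math.isfinite(self.age) and self.age >= 0):
            raise ValidationError(f"age={self.age} must be >= 0")
        _check_range("height", self.height, *HEIGHT_RANGE_M)
        _check_range("weight", self.weight, *WEIGHT_RANGE_KG)
        _check_range("resistance", self.resistance, *RESISTANCE_RANGE_OHM)
        _check_range("reactance", self.reactance, *REACTANCE_RANGE_OHM, lo_inclusive=True)
        if self.reference_asm is not None and not (
            math.isfinite(self.reference_asm) and self.reference_asm > 0
        ):
            raise ValidationError(f"reference_asm={self.reference_asm} must be positive")

    @property
    def sex_code(self) -> int:
        return sex_code(self.sex)

    @property
    def bmi(self) -> float:
        return compute_bmi(self.weight, self.height)

    @property
    def bmi_band(self) -> BMIBand:
        return bmi_band(self.bmi)

    @property
    def impedance(self) -> float:
        return impedance_z(self.resistance, self.reactance)

    def index(self, kind: IndexKind | str = IndexKind.HT2_OVER_R) -> float:
        return impedance_index(self.height, self.resistance, kind, self.reactance)
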