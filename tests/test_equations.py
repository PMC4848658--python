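import dataclasses

import numpy as np
import pandas as pd
import pytest
from sklearn.pipeline import Pipeline

from bia_asm import (
    ASMPredictor,
    EQUATION_NAMES,
    SubjectRecord,
    ValidationError,
    predict_asm,
    predict_records,
    registry_self_test,
)

from _oracle import ALL as ORACLE
from conftest import random_records

# hand-computed expected ASM (kg) for the worked subject:
# male, 40 yr, 1.70 m, 70 kg, R 500 Ohm, Xc 50 Ohm
WORKED_EXPECTED = {
    "sergi": 20.3906,
    "kyle": 22.2006,
    "peniche": 21.0416,
    "kim": 16.4782,
    "yoshida": 23.841,  # Ht^2/Z convention
}


def test_registry_matches_published_transcription():
    registry_self_test()


@pytest.mark.parametrize("equation", EQUATION_NAMES)
def test_worked_subject_matches_hand_arithmetic(worked_subject, equation):
    assert predict_asm(worked_subject, equation) == pytest.approx(
        WORKED_EXPECTED[equation], abs=5e-4
    )


@pytest.mark.parametrize("equation", EQUATION_NAMES)
def test_equations_match_independent_oracle(equation):
    """Registry evaluation agrees with standalone direct arithmetic to 1e-9 kg."""
    records = random_records(1000, seed=101)
    got = predict_records(records, equation)
    expected = np.array(
        [
            ORACLE[equation](r.sex.value, r.age, r.height, r.weight, r.resistance, r.reactance)
            for r in records
        ]
    )
    np.testing.assert_allclose(got, expected, atol=1e-9, rtol=0)


def test_yoshida_r_convention_matches_oracle():
    records = random_records(200, seed=102)
    got = predict_records(records, "yoshida", yoshida_index="r")
    expected = np.array(
        [
            ORACLE["yoshida"](r.sex.value, r.age, r.height, r.weight, r.resistance, r.reactance, "r")
            for r in records
        ]
    )
    np.testing.assert_allclose(got, expected, atol=1e-9, rtol=0)


SEX_OFFSETS = {"sergi": 1.384, "kyle": 1.909, "peniche": 2.708, "kim": 2.954}


@pytest.mark.parametrize("equation,offset", sorted(SEX_OFFSETS.items()))
def test_male_female_offset_is_exactly_the_sex_coefficient(equation, offset):
    for rec in random_records(50, seed=103):
        male = dataclasses.replace(rec, sex="male")
        female = dataclasses.replace(rec, sex="female")
        diff = predict_asm(male, equation) - predict_asm(female, equation)
        assert diff == pytest.approx(offset, abs=1e-12)


@pytest.mark.parametrize("equation", EQUATION_NAMES)
def test_strictly_increasing_in_weight(equation):
    for rec in random_records(30, seed=104):
        if rec.weight + 1.0 >= 300:
            continue
        heavier = dataclasses.replace(rec, weight=rec.weight + 1.0)
        assert predict_asm(heavier, equation) > predict_asm(rec, equation)


@pytest.mark.parametrize(
    "equation,slope",
    [("kyle", -0.012), ("kim", -0.050), ("sergi", 0.0), ("peniche", 0.0), ("yoshida", 0.0)],
)
def test_age_dependence(equation, slope):
    """Kyle and Kim decline linearly with age; the others are age-invariant."""
    for rec in random_records(20, seed=105):
        older = dataclasses.replace(rec, age=rec.age + 10.0)
        diff = predict_asm(older, equation) - predict_asm(rec, equation)
        assert diff == pytest.approx(10.0 * slope, abs=1e-10)


def test_cohort_mean_plugin_close_to_published_male_mean():
    """Male cohort means pushed through the Sergi equation land within
    0.5 kg of the published male mean predicted ASM (24.74 kg), validating
    the cm-based Ht^2/R index direction over the inverted footnote reading."""
    means = SubjectRecord("means", "male", 48.0, 1.8, 85.3, 456.1, 54.3)
    assert abs(predict_asm(means, "sergi") - 24.74) < 0.5


def test_unknown_equation_rejected():
    rec = random_records(1, seed=1)[0]
    with pytest.raises(ValidationError, match="sergi"):
        predict_asm(rec, "nonexistent")


class TestASMPredictorEstimator:
    def frame(self, n=20, seed=9):
        recs = random_records(n, seed)
        return pd.DataFrame(
            {
                "sex": [r.sex.value for r in recs],
                "age": [r.age for r in recs],
                "height_m": [r.height for r in recs],
                "weight_kg": [r.weight for r in recs],
                "resistance_ohm": [r.resistance for r in recs],
                "reactance_ohm": [r.reactance for r in recs],
            }
        )

    def test_fit_predict_matches_record_path(self):
        X = self.frame()
        est = ASMPredictor(equation="kyle").fit(X)
        assert est.n_features_in_ == X.shape[1]
        recs = [
            SubjectRecord(str(i), row.sex, row.age, row.height_m, row.weight_kg,
                          row.resistance_ohm, row.reactance_ohm)
            for i, row in enumerate(X.itertuples(index=False))
        ]
        np.testing.assert_allclose(est.predict(X), predict_records(recs, "kyle"), atol=1e-12)

    def test_get_set_params_roundtrip_and_clone_compat(self):
        est = ASMPredictor(equation="yoshida", yoshida_index="r")
        params = est.get_params()
        assert params == {"equation": "yoshida", "yoshida_index": "r"}
        est.set_params(equation="sergi")
        assert est.equation == "sergi"

    def test_works_inside_sklearn_pipeline(self):
        X = self.frame()
        pipe = Pipeline([("asm", ASMPredictor(equation="sergi"))])
        got = pipe.fit(X).predict(X)
        assert got.shape == (len(X),)

    def test_missing_column_named_in_error(self):
        X = self.frame().drop(columns=["resistance_ohm"])
        with pytest.raises(ValidationError, match="resistance_ohm"):
            ASMPredictor().fit(X)

    def test_predict_before_fit_raises(self):
        with pytest.raises(ValidationError, match="not fitted"):
            ASMPredictor().predict(self.frame())
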