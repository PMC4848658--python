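import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from bia_asm import (
    InsufficientDataError,
    PairedSeries,
    UndefinedCorrelationError,
    bland_altman,
    compare,
    mean_error,
    pearson,
    rmse,
    rmse_bootstrap_ci,
)

finite = st.floats(min_value=-50, max_value=50, allow_nan=False, allow_infinity=False)
vectors = arrays(np.float64, st.integers(min_value=3, max_value=60), elements=finite)


def make_pairs(diffs, base=20.0):
    d = np.asarray(diffs, float)
    ref = np.full_like(d, base)
    return PairedSeries(ref + d, ref)


class TestMeanError:
    def test_hand_computed_example(self):
        me, ci, p = mean_error(make_pairs([1, -1, 0, 2]))
        assert me == pytest.approx(0.5)
        assert ci[0] < me < ci[1]
        # cross-check the paired-t p against a one-sample t on the differences
        assert p == pytest.approx(stats.ttest_1samp([1, -1, 0, 2], 0).pvalue)

    def test_identity_pairs_are_degenerate(self):
        me, ci, p = mean_error(make_pairs([0, 0, 0]))
        assert (me, ci, p) == (0.0, (0.0, 0.0), 1.0)
        result = compare(make_pairs([0, 0, 0]))
        assert result.degenerate_variance and result.mean_error == 0.0

    def test_constant_shift_is_degenerate_with_nonzero_bias(self):
        me, ci, p = mean_error(make_pairs([2.5, 2.5, 2.5]))
        assert me == pytest.approx(2.5) and ci == (2.5, 2.5) and p == 0.0

    def test_single_pair_rejected(self):
        with pytest.raises(InsufficientDataError):
            PairedSeries(np.array([1.0]), np.array([1.0]))


class TestRMSE:
    def test_hand_computed_example(self):
        value, ci = rmse(make_pairs([1, -1, 0, 2]))
        assert value == pytest.approx(np.sqrt(1.5))
        assert 0 <= ci[0] <= value <= ci[1]

    def test_identity_and_constant_cases(self):
        assert rmse(make_pairs([0, 0, 0, 0]))[0] == 0.0
        assert rmse(make_pairs([-3, -3, -3]))[0] == pytest.approx(3.0)

    def test_bootstrap_ci_brackets_rmse_and_is_seed_stable(self):
        rng = np.random.default_rng(5)
        pairs = make_pairs(rng.normal(-1, 2, 300))
        value, _ = rmse(pairs)
        ci1 = rmse_bootstrap_ci(pairs, seed=11)
        ci2 = rmse_bootstrap_ci(pairs, seed=11)
        assert ci1 == ci2
        assert ci1[0] < value < ci1[1]


class TestBlandAltman:
    def test_identity_pairs_have_zero_width(self):
        assert bland_altman(make_pairs([0.0, 0.0, 0.0])) == (0.0, 0.0)

    def test_unit_normal_scale(self):
        # differences engineered to ME = 0, sd = 1 exactly
        d = np.array([-1.0, 1.0, -1.0, 1.0, 0.0])
        d = d / d.std(ddof=1)
        lo, hi = bland_altman(make_pairs(d))
        assert (lo, hi) == pytest.approx((-1.96, 1.96))

    def test_monte_carlo_limits_match_closed_form(self):
        rng = np.random.default_rng(12345)
        pairs = make_pairs(rng.normal(-1.0, 2.0, 100_000))
        lo, hi = bland_altman(pairs)
        assert lo == pytest.approx(-1.0 - 1.96 * 2.0, abs=0.05)
        assert hi == pytest.approx(-1.0 + 1.96 * 2.0, abs=0.05)

    def test_empirical_coverage_is_95_percent(self):
        rng = np.random.default_rng(777)
        d = rng.normal(0.4, 1.7, 100_000)
        lo, hi = bland_altman(make_pairs(d))
        coverage = np.mean((d >= lo) & (d <= hi))
        assert coverage == pytest.approx(0.95, abs=0.005)


class TestPearson:
    def test_perfect_and_reversed_agreement(self):
        ref = np.array([10.0, 15.0, 20.0, 25.0])
        assert pearson(PairedSeries(ref, ref))[0] == pytest.approx(1.0)
        assert pearson(PairedSeries(-ref, ref))[0] == pytest.approx(-1.0)

    def test_affine_invariance(self):
        ref = np.array([10.0, 12.0, 19.0, 30.0, 8.0])
        assert pearson(PairedSeries(3.2 * ref + 4.0, ref))[0] == pytest.approx(1.0)

    def test_constant_series_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson(PairedSeries(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0])))


@settings(deadline=None, derandomize=True, max_examples=200)
@given(vectors)
def test_rmse_me_sd_identity(d):
    """RMSE^2 = ME^2 + sd_diff^2 * (n-1)/n holds exactly for any differences."""
    pairs = make_pairs(d)
    n = pairs.n
    me = mean_error(pairs)[0]
    value = rmse(pairs)[0]
    sd = float(d.std(ddof=1))
    assert value**2 == pytest.approx(me**2 + sd**2 * (n - 1) / n, abs=1e-9)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(vectors, st.randoms(use_true_random=False))
def test_statistics_are_permutation_invariant(d, rnd):
    pairs = make_pairs(d)
    order = list(range(len(d)))
    rnd.shuffle(order)
    shuffled = PairedSeries(pairs.predicted[order], pairs.reference[order])
    assert mean_error(shuffled)[0] == pytest.approx(mean_error(pairs)[0], abs=1e-12)
    assert rmse(shuffled)[0] == pytest.approx(rmse(pairs)[0], abs=1e-12)
    assert bland_altman(shuffled) == pytest.approx(bland_altman(pairs), abs=1e-10)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(
    arrays(np.float64, 12, elements=finite),
    st.floats(min_value=0.1, max_value=10),
    st.floats(min_value=-20, max_value=20),
)
def test_pearson_invariant_under_positive_affine_transform(ref, a, b):
    rng = np.random.default_rng(3)
    pred = ref + rng.normal(0, 1, ref.size)
    if np.ptp(ref) < 1e-6 or np.ptp(pred) < 1e-6:
        return
    r0 = pearson(PairedSeries(pred, ref))[0]
    r1 = pearson(PairedSeries(a * pred + b, ref))[0]
    assert r1 == pytest.approx(r0, abs=1e-9)


def test_compare_result_invariants_on_random_data():
    rng = np.random.default_rng(21)
    for _ in range(50):
        pairs = make_pairs(rng.normal(rng.normal(), rng.uniform(0.2, 3), rng.integers(5, 80)))
        res = compare(pairs)
        assert res.rmse >= abs(res.mean_error) - 1e-12
        assert res.me_ci[0] <= res.mean_error <= res.me_ci[1]
        assert res.rmse_ci[0] <= res.rmse <= res.rmse_ci[1]
        assert res.loa == pytest.approx(
            (res.mean_error - 1.96 * res.sd_diff, res.mean_error + 1.96 * res.sd_diff)
        )
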