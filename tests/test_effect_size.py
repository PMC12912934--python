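"""Unit and property tests for the standardized effect-size machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from espi.effect_size import (
    GroupSample,
    cohens_d,
    correction_factor_approx,
    correction_factor_exact,
    harmonic_n,
    hedges_g,
    noncentral_ci,
    pooled_sd,
    true_standard_error,
)
from espi.exceptions import DegenerateVarianceError, InvalidInputError


def _group_with(mean, sd, n, rng):
    """Sample with exactly the requested mean and sample SD."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return GroupSample(mean + sd * x)


class TestGroupSample:
    def test_drops_missing_values(self):
        g = GroupSample.from_values([1.0, np.nan, 2.0, np.inf, 3.0])
        assert g.n == 3
        np.testing.assert_array_equal(g.values, [1.0, 2.0, 3.0])

    def test_rejects_fewer_than_two(self):
        with pytest.raises(InvalidInputError):
            GroupSample([1.0])

    def test_rejects_raw_nan(self):
        with pytest.raises(InvalidInputError):
            GroupSample([1.0, np.nan])


class TestPooledSD:
    def test_equal_sds_pool_to_themselves(self, rng):
        a = _group_with(0, 2.0, 7, rng)
        b = _group_with(5, 2.0, 12, rng)
        assert pooled_sd(a, b) == pytest.approx(2.0)

    def test_hand_computed_unequal_sds(self, rng):
        # S1=1, S2=3, n1=n2=10 -> sqrt((9*1 + 9*9)/18) = sqrt(5)
        a = _group_with(0, 1.0, 10, rng)
        b = _group_with(0, 3.0, 10, rng)
        assert pooled_sd(a, b) == pytest.approx(np.sqrt(5.0), rel=1e-12)

    def test_constant_groups_pool_to_zero(self):
        a = GroupSample([4.0, 4.0, 4.0])
        b = GroupSample([7.0, 7.0])
        assert pooled_sd(a, b) == 0.0
        with pytest.raises(DegenerateVarianceError):
            cohens_d(a, b)


class TestCohensD:
    def test_identical_groups_give_zero(self):
        a = GroupSample([1.0, 2.0, 3.0])
        assert cohens_d(a, a) == 0.0

    def test_hand_computed(self, rng):
        # means 3 and 1 with pooled SD 2 -> d = 1
        a = _group_with(3.0, 2.0, 8, rng)
        b = _group_with(1.0, 2.0, 8, rng)
        assert cohens_d(a, b) == pytest.approx(1.0, rel=1e-12)

    def test_antisymmetry(self, rng):
        a = GroupSample(rng.normal(0, 1, 9))
        b = GroupSample(rng.normal(1, 2, 14))
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a), rel=1e-14)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(2, 15, size=2)
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), n1)
            y = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), n2)
            sp = np.sqrt(
                ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1))
                / (n1 + n2 - 2)
            )
            expected = (np.mean(x) - np.mean(y)) / sp
            got = cohens_d(GroupSample(x), GroupSample(y))
            assert got == pytest.approx(expected, rel=1e-12)


class TestCorrectionFactor:
    def test_exact_at_v10(self):
        assert correction_factor_exact(10) == pytest.approx(0.9227, abs=5e-5)

    def test_exact_at_v2_closed_form(self):
        assert correction_factor_exact(2) == pytest.approx(1 / np.sqrt(np.pi), rel=1e-12)

    def test_approx_at_v10(self):
        assert correction_factor_approx(10) == pytest.approx(0.923077, abs=5e-7)

    def test_exact_and_approx_nearly_agree_at_v10(self):
        diff = abs(correction_factor_exact(10) - correction_factor_approx(10))
        assert diff < 5e-4

    def test_asymptotic_limit(self):
        assert correction_factor_exact(10**6) == pytest.approx(1.0, abs=1e-5)
        assert correction_factor_approx(10**6) == pytest.approx(1.0, abs=1e-5)

    def test_exact_monotone_increasing_below_one(self):
        vals = [correction_factor_exact(v) for v in range(2, 200)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(0 < v < 1 for v in vals)

    @pytest.mark.parametrize("v", [10, 15, 30, 60, 120, 500])
    def test_exact_below_approx_within_1e3(self, v):
        exact, approx = correction_factor_exact(v), correction_factor_approx(v)
        assert exact < approx
        assert approx - exact < 1e-3

    @pytest.mark.parametrize("fn", [correction_factor_exact, correction_factor_approx])
    def test_rejects_v_below_two(self, fn):
        with pytest.raises(InvalidInputError):
            fn(1)


class TestHedgesG:
    def test_zero_for_identical_groups(self):
        a = GroupSample([1.0, 2.0, 3.0, 4.0])
        eff = hedges_g(a, a)
        assert eff.g == 0.0
        assert eff.ci_low <= 0.0 <= eff.ci_high

    def test_g_strictly_shrinks_d(self, rng):
        a = GroupSample(rng.normal(0, 1, 6))
        b = GroupSample(rng.normal(2, 1, 6))
        eff = hedges_g(a, b)
        assert abs(eff.g) < abs(eff.d)
        assert eff.g == pytest.approx(eff.d * eff.j, rel=1e-14)

    def test_record_invariants(self, rng):
        a = GroupSample(rng.normal(0, 1, 7))
        b = GroupSample(rng.normal(1, 2, 11))
        eff = hedges_g(a, b)
        assert eff.v == 16
        assert eff.n_harmonic == pytest.approx(harmonic_n(7, 11))
        assert eff.ci_low <= eff.g <= eff.ci_high

    def test_against_independent_reference_at_v10(self, rng):
        # n1 = n2 = 6: g must equal brute-force d times J(10)
        x = rng.normal(1, 1, 6)
        y = rng.normal(0, 1, 6)
        sp = np.sqrt((np.var(x, ddof=1) + np.var(y, ddof=1)) / 2)
        d_ref = (x.mean() - y.mean()) / sp
        eff = hedges_g(GroupSample(x), GroupSample(y))
        assert eff.g == pytest.approx(d_ref * correction_factor_exact(10), rel=1e-12)

    def test_matches_pingouin_approx_correction(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(0.5, 1.2, 12)
        y = rng.normal(0.0, 0.8, 9)
        eff = hedges_g(GroupSample(x), GroupSample(y), exact=False)
        ref = pingouin.compute_effsize(x, y, eftype="hedges")
        assert eff.g == pytest.approx(ref, rel=1e-10)

    @settings(max_examples=50, deadline=None)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_scale_invariance(self, scale, seed):
        r = np.random.default_rng(seed)
        x = r.normal(0, 1, 8)
        y = r.normal(1, 1.5, 10)
        e1 = hedges_g(GroupSample(x), GroupSample(y))
        e2 = hedges_g(GroupSample(x * scale), GroupSample(y * scale))
        assert e2.g == pytest.approx(e1.g, rel=1e-10)
        assert e2.se == pytest.approx(e1.se, rel=1e-10)
        assert e2.ci_low == pytest.approx(e1.ci_low, rel=1e-9, abs=1e-12)
        assert e2.ci_high == pytest.approx(e1.ci_high, rel=1e-9, abs=1e-12)

    def test_antisymmetry_mirrors_ci(self, rng):
        a = GroupSample(rng.normal(0, 1, 9))
        b = GroupSample(rng.normal(1, 1, 9))
        e_ab, e_ba = hedges_g(a, b), hedges_g(b, a)
        assert e_ba.g == pytest.approx(-e_ab.g, rel=1e-12)
        assert e_ba.ci_low == pytest.approx(-e_ab.ci_high, rel=1e-6)
        assert e_ba.ci_high == pytest.approx(-e_ab.ci_low, rel=1e-6)


class TestTrueStandardError:
    def test_increases_with_effect_magnitude(self):
        ses = [true_standard_error(g, 10, 10) for g in (0.0, 0.5, 1.0, 2.0)]
        assert all(b > a for a, b in zip(ses, ses[1:]))

    def test_vanishes_with_large_samples(self):
        ses = [true_standard_error(1.0, n, n) for n in (10, 100, 1000, 10000)]
        assert all(b < a for a, b in zip(ses, ses[1:]))
        assert ses[-1] < 0.02

    def test_rejects_tiny_df(self):
        with pytest.raises(InvalidInputError):
            true_standard_error(1.0, 2, 2)


class TestNoncentralCI:
    def test_symmetric_about_zero_for_null_effect(self):
        lo, hi = noncentral_ci(0.0, 10, 10)
        # root-finding precision of the quantile inversion is ~1e-8
        assert lo == pytest.approx(-hi, abs=1e-6)
        assert lo < 0 < hi

    def test_nesting_of_levels(self):
        lo50, hi50 = noncentral_ci(0.8, 10, 12, level=0.50)
        lo95, hi95 = noncentral_ci(0.8, 10, 12, level=0.95)
        assert lo95 < lo50 < hi50 < hi95

    def test_interval_brackets_g(self, rng):
        for _ in range(20):
            g = rng.uniform(-3, 3)
            n1, n2 = rng.integers(4, 30, size=2)
            lo, hi = noncentral_ci(g, int(n1), int(n2))
            assert lo <= g <= hi

    def test_rejects_bad_level(self):
        with pytest.raises(InvalidInputError):
            noncentral_ci(0.5, 10, 10, level=1.2)
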