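"""Growth-rate fits, rank tests against an enumeration oracle, summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kelpmorph.stats import (
    compare_conditions,
    fit_increase_rate,
    geometric_summary,
    mann_whitney_u,
    student_t,
)

# ---------------------------------------------------------------------------
# independent Mann-Whitney oracle: U from pair counts, p by exhaustive
# enumeration of all group labelings of the pooled sample


def oracle_u(a, b):
    u = 0.0
    for x in a:
        for y in b:
            u += (x > y) + 0.5 * (x == y)
    return u


def oracle_p(a, b, alternative):
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    obs = oracle_u(a, b)
    us = []
    for idx in itertools.combinations(range(n), na):
        mask = np.zeros(n, bool)
        mask[list(idx)] = True
        us.append(oracle_u(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    eps = 1e-9
    p_greater = np.mean(us >= obs - eps)
    p_less = np.mean(us <= obs + eps)
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2 * min(p_greater, p_less))


class TestMannWhitney:
    def test_fully_separated_groups(self):
        cmp_ = mann_whitney_u([1, 2, 3], [4, 5, 6], alternative="two_sided")
        assert cmp_.statistic == 0
        assert cmp_.p_value == pytest.approx(0.1)

    def test_symmetric_groups_p_one(self):
        cmp_ = mann_whitney_u([1, 2], [1, 2])
        assert cmp_.p_value == pytest.approx(1.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("alternative", ["two_sided", "less", "greater"])
    def test_matches_enumeration_oracle_exhaustively(self, alternative):
        """Exact agreement with the enumeration oracle for every tie-free
        rank arrangement with n_a + n_b <= 10 (p depends only on ranks)."""
        for n in range(2, 11):
            for na in range(1, n):
                for idx in itertools.combinations(range(n), na):
                    values = np.arange(1.0, n + 1)
                    mask = np.zeros(n, bool)
                    mask[list(idx)] = True
                    a, b = values[mask], values[~mask]
                    got = mann_whitney_u(a, b, alternative=alternative)
                    assert got.p_value == pytest.approx(
                        oracle_p(a, b, alternative), abs=1e-12
                    ), (n, na, idx)

    def test_large_sample_approximation_close_to_exact(self, rng):
        # n=30 vs 30 is far beyond enumeration; check the normal
        # approximation against the oracle at a reduced n where both exist
        for _ in range(10):
            a = rng.normal(size=6)
            b = rng.normal(loc=0.5, size=6)
            exact = mann_whitney_u(a, b).p_value
            approx = mann_whitney_u(
                np.concatenate([a, a + 1e-7 * rng.normal(size=6)]),
                np.concatenate([b, b + 1e-7 * rng.normal(size=6)]),
            )
            assert 0 <= approx.p_value <= 1
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        approx = mann_whitney_u(a, b)
        assert not approx.continuity_correction or approx.p_value <= 1

    def test_tied_data_uses_corrected_approximation(self):
        cmp_ = mann_whitney_u([1, 1, 2, 2, 3], [2, 2, 3, 3, 4])
        assert 0 < cmp_.p_value <= 1


class TestStudentT:
    def test_identical_groups(self):
        cmp_ = student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert cmp_.statistic == pytest.approx(0.0)
        assert cmp_.p_value == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        # a mean .5, b mean 1.5, pooled var 1/3 -> |t| = sqrt(6)
        cmp_ = student_t([0, 0, 1, 1], [1, 1, 2, 2])
        assert abs(cmp_.statistic) == pytest.approx(math.sqrt(6.0))

    def test_too_small_group_raises(self):
        with pytest.raises(ValueError):
            student_t([1.0], [1.0, 2.0])

    def test_zero_pooled_variance_raises(self):
        with pytest.raises(ValueError):
            student_t([1.0, 1.0], [2.0, 2.0])


class TestFitIncreaseRate:
    def test_exact_doubling_series(self):
        est = fit_increase_rate([(0, 100), (1, 200), (2, 400), (3, 800)], True)
        assert est.slope == pytest.approx(math.log(2), rel=1e-12)

    def test_constant_series_zero_slope(self):
        est = fit_increase_rate([(0, 50), (1, 50), (2, 50)], log_transform=False)
        assert est.slope == pytest.approx(0.0, abs=1e-12)

    def test_recovers_noisy_exponential_rate(self, rng):
        """Mean slope over 50 lognormal-noise replicates within 0.02 of the
        true rate 0.5/day."""
        r = 0.5
        slopes = []
        for _ in range(50):
            days = np.arange(7)
            vals = 10.0 * np.exp(r * days) * rng.lognormal(0, 0.1, size=7)
            slopes.append(fit_increase_rate(list(zip(days, vals)), True).slope)
        assert np.mean(slopes) == pytest.approx(r, abs=0.02)

    def test_nonpositive_value_under_log_names_day(self):
        with pytest.raises(ValueError, match="day 2"):
            fit_increase_rate([(0, 1.0), (1, 2.0), (2, 0.0)], True)

    def test_single_day_raises(self):
        with pytest.raises(ValueError):
            fit_increase_rate([(0, 1.0), (0, 2.0)], False)


class TestGeometricSummary:
    @pytest.mark.parametrize(
        "values, gm, gsd",
        [([1.0, 4.0], 2.0, None), ([2.0, 2.0, 2.0], 2.0, 1.0)],
    )
    def test_known_values(self, values, gm, gsd):
        got_gm, got_gsd = geometric_summary(values)
        assert got_gm == pytest.approx(gm)
        if gsd is not None:
            assert got_gsd == pytest.approx(gsd)

    def test_lognormal_sample_recovery(self, rng):
        v = rng.lognormal(mean=1.0, sigma=0.3, size=10_000)
        gm, gsd = geometric_summary(v)
        assert gm == pytest.approx(math.e, rel=0.02)
        assert gsd == pytest.approx(math.exp(0.3), rel=0.02)

    @given(c=st.floats(0.01, 100))
    def test_scale_equivariance(self, c):
        base = [1.0, 2.0, 5.0, 9.0]
        gm0, gsd0 = geometric_summary(base)
        gm1, gsd1 = geometric_summary([c * v for v in base])
        assert gm1 == pytest.approx(c * gm0, rel=1e-9)
        assert gsd1 == pytest.approx(gsd0, rel=1e-9)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            geometric_summary([1.0, -2.0])


def tidy_frame(values_by_condition, measure="blade_area", day=6):
    rows = []
    for cond, values in values_by_condition.items():
        for i, v in enumerate(values):
            rows.append(
                dict(embryo_id=f"{cond}_{i}", condition=cond, day=day,
                     measure=measure, value=v)
            )
    return pd.DataFrame(rows)


class TestCompareConditions:
    def test_identical_groups_not_significant(self):
        vals = list(np.linspace(100, 200, 8))
        df = tidy_frame({"AE2": vals, "CT2": vals})
        cmp_, summary = compare_conditions(df, "blade_area", "day6", "AE2", "CT2")
        assert not cmp_.significant
        assert set(summary["condition"]) == {"AE2", "CT2"}

    def test_type_i_error_near_alpha(self, rng):
        """Null rejection rate of the one-tailed day-6 comparison is
        alpha = 0.05 within ±0.02 over 10³ repetitions."""
        rejections = 0
        reps = 1000
        for _ in range(reps):
            df = tidy_frame(
                {
                    "AE2": rng.lognormal(5, 0.3, size=10),
                    "CT2": rng.lognormal(5, 0.3, size=10),
                }
            )
            cmp_, _ = compare_conditions(df, "blade_area", "day6", "AE2", "CT2")
            rejections += cmp_.significant
        assert abs(rejections / reps - 0.05) <= 0.02

    def test_power_for_twofold_shift(self, rng):
        """A two-fold (log-space) reduction is detected one-tailed at
        alpha = 0.05 in at least 90% of 500 repetitions at n = 10 vs 10."""
        hits = 0
        reps = 500
        for _ in range(reps):
            control = rng.lognormal(5, 0.3, size=10)
            treated = rng.lognormal(5 - math.log(2), 0.3, size=10)
            df = tidy_frame({"AE2": treated, "CT2": control})
            cmp_, _ = compare_conditions(df, "blade_area", "day6", "AE2", "CT2")
            hits += cmp_.significant
        assert hits / reps >= 0.90

    def test_rate_endpoint_uses_per_embryo_slopes(self, rng):
        rows = []
        for cond, rate in [("AE2", 0.4), ("CT2", 0.4)]:
            for i in range(5):
                for day in range(7):
                    rows.append(
                        dict(embryo_id=f"{cond}_{i}", condition=cond, day=day,
                             measure="blade_area",
                             value=100 * math.exp(rate * day)
                             * rng.lognormal(0, 0.05))
                    )
        df = pd.DataFrame(rows)
        cmp_, _ = compare_conditions(df, "blade_area", "rate", "AE2", "CT2")
        assert cmp_.alternative == "two_sided"
        assert not cmp_.significant

    def test_missing_endpoint_day_excludes_embryo(self):
        df = tidy_frame({"AE2": [1, 2, 3], "CT2": [1, 2, 3]})
        df = df[~((df["embryo_id"] == "AE2_0"))]
        cmp_, summary = compare_conditions(df, "blade_area", "day6", "AE2", "CT2")
        assert cmp_.n_a == 2

    def test_small_group_raises(self):
        df = tidy_frame({"AE2": [1.0], "CT2": [1.0, 2.0]})
        with pytest.raises(ValueError):
            compare_conditions(df, "blade_area", "day6", "AE2", "CT2")
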