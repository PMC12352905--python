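import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hnfscore.stats import (
    arm_fold_changes,
    arm_volume_ratio,
    fisher_exact_2x2,
    growth_fold_change,
    km_estimator,
    logrank_test,
    median_survival,
    pearson_correlation,
    tumor_volume,
)


class TestFisherExact:
    def test_printed_response_table(self):
        # High: 4 nonresponders / 1 responder; Low: 3 / 17
        assert round(fisher_exact_2x2(4, 1, 3, 17), 3) == 0.012

    def test_empty_column_is_uninformative(self):
        assert fisher_exact_2x2(0, 5, 0, 20) == 1.0

    def test_small_table_enumeration(self):
        # margins (2,2)x(2,2): P(k)=C(2,k)C(2,2-k)/C(4,2) for k=0,1,2
        # = 1/6, 4/6, 1/6; outcomes as extreme as k=2: {0,2} -> 2/6
        assert fisher_exact_2x2(2, 0, 0, 2) == pytest.approx(1 / 3)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b + c + d == 0:
                continue
            _, p_ref = sps.fisher_exact([[a, b], [c, d]])
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(p_ref, abs=1e-9)


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimator([1, 2, 3], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.survival_at(10) == 1.0

    def test_single_event_among_four(self):
        curve = km_estimator([2, 5, 6, 7], [1, 0, 0, 0])
        assert curve.survival_at(2) == pytest.approx(0.75)

    def test_hand_product_limit_with_censoring(self):
        # events at 1, 2, 4; censor at 3. n at risk: 4, 3, 1.
        # S = 3/4, 3/4*2/3 = 1/2, then (1 - 1/1) -> 0.
        curve = km_estimator([1, 2, 3, 4], [1, 1, 0, 1])
        assert curve.survival_at(1) == pytest.approx(0.75)
        assert curve.survival_at(2) == pytest.approx(0.50)
        assert curve.survival_at(4) == pytest.approx(0.0)
        assert list(curve.at_risk) == [4, 3, 1]

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(10, size=60).round(1)
        e = rng.integers(0, 2, size=60)
        curve = km_estimator(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for et, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(kmf.predict(et), abs=1e-9)

    def test_no_censoring_equals_empirical_survivor(self, rng):
        t = rng.exponential(5, size=40)
        curve = km_estimator(t, np.ones(40, dtype=int))
        for q in (2.0, 5.0, 9.0):
            assert curve.survival_at(q) == pytest.approx((t > q).mean())

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimator([-1, 2], [1, 1])


class TestMedianSurvival:
    def test_exact_half_crossing(self):
        # S(2) = 0.5 exactly; median is the smallest t with S(t) <= 0.5
        curve = km_estimator([2, 6], [1, 1])
        assert median_survival(curve) == 2

    def test_undefined_when_curve_stays_high(self):
        curve = km_estimator([1, 2, 3, 4, 5], [1, 0, 0, 0, 0])
        assert median_survival(curve) is None

    def test_read_off_three_event_toy(self):
        curve = km_estimator([1, 2, 3], [1, 1, 1])
        # S = 2/3, 1/3, 0 -> first <= 0.5 at t=2
        assert median_survival(curve) == 2

    def test_exponential_median_approaches_ln2_over_lambda(self, rng):
        lam = 0.2
        t = rng.exponential(1 / lam, size=4000)
        curve = km_estimator(t, np.ones_like(t, dtype=int))
        assert median_survival(curve) == pytest.approx(np.log(2) / lam, rel=0.1)


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 1, 0, 1, 1, 1, 0]
        g = list("aaaabbbb")
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_invariant_under_group_relabeling(self, rng):
        t = rng.exponential(10, size=40)
        e = rng.integers(0, 2, size=40)
        g = np.array(["x"] * 20 + ["y"] * 20)
        stat1, _ = logrank_test(t, e, g)
        swapped = np.where(g == "x", "y", "x")
        stat2, _ = logrank_test(t, e, swapped)
        assert stat1 == pytest.approx(stat2)

    def test_all_censored_returns_null(self):
        stat, p = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])
        assert (stat, p) == (0.0, 1.0)

    def test_two_group_toy_matches_direct_oe_tally(self):
        # group a: events at 1, 2; group b: event at 3, censor at 4
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 0])
        g = np.array(["a", "a", "b", "b"])
        # t=1: n=4 (2a,2b), d=1 in a; E_a=1/2, V=(2*2*1*3)/(16*3)=1/4
        # t=2: n=3 (1a,2b), d=1 in a; E_a=1/3, V=(1*2*1*2)/(9*2)=2/9
        # t=3: n=2 (0a,2b), d=1 in b; E_a=0,  V=0
        o_minus_e = (1 - 0.5) + (1 - 1 / 3) + (0 - 0)
        v = 0.25 + 2 / 9
        expected = o_minus_e**2 / v
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(expected)
        assert p == pytest.approx(sps.chi2.sf(expected, 1))

    def test_matches_lifelines_multigroup(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        t = rng.exponential(10, size=90)
        e = rng.integers(0, 2, size=90)
        g = rng.choice(["a", "b", "c"], size=90)
        stat, p = logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)


class TestPearson:
    def test_perfect_positive(self):
        r, _ = pearson_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_affine_antimonotone(self):
        x = np.array([1.0, 2.0, 5.0])
        r, _ = pearson_correlation(x, -2 * x + 5)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        r, p = pearson_correlation(x, y)
        assert r == pytest.approx(expected)
        assert 0 < p <= 1

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestTumorGrowth:
    @pytest.mark.parametrize("dims, expected", [((6, 1, 1), 1.0), ((3, 2, 1), 1.0), ((10, 8, 6), 80.0)])
    def test_volume_formula(self, dims, expected):
        assert tumor_volume(*dims) == pytest.approx(expected)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            tumor_volume(1, 2, 3)  # D < d
        with pytest.raises(ValueError):
            tumor_volume(3, 2, 0)

    def _records(self):
        return pd.DataFrame(
            {
                "animal": ["m1"] * 3 + ["m2"] * 3,
                "arm": ["vehicle"] * 3 + ["vehicle"] * 3,
                "day": [0, 14, 28, 0, 14, 28],
                "volume_mm3": [100, 150, 100, 100, 200, 250],
            }
        )

    def test_fold_change_vs_day0(self):
        fc = growth_fold_change(self._records(), "m1")
        assert fc[28] == pytest.approx(1.0)
        fc2 = growth_fold_change(self._records(), "m2")
        assert fc2[28] == pytest.approx(2.5)

    def test_missing_day0_rejected(self):
        rec = self._records()
        rec = rec[rec["day"] != 0]
        with pytest.raises(ValueError, match="day-0"):
            growth_fold_change(rec, "m1")

    def test_arm_mean_sem_matches_direct_computation(self):
        out = arm_fold_changes(self._records(), "vehicle", 28)
        per_animal = np.array([1.0, 2.5])
        assert out["mean_fold_change"].iloc[0] == pytest.approx(per_animal.mean())
        assert out["sem"].iloc[0] == pytest.approx(per_animal.std(ddof=1) / np.sqrt(2))

    def test_identical_arms_ratio_one(self):
        rec = self._records()
        treated = rec.copy()
        treated["arm"] = "pelabresib"
        treated["animal"] = treated["animal"] + "_t"
        both = pd.concat([rec, treated])
        assert arm_volume_ratio(both, "pelabresib", "vehicle", 28) == pytest.approx(1.0)

    def test_static_treated_vs_doubled_vehicle(self):
        rec = pd.DataFrame(
            {
                "animal": ["t1", "t1", "v1", "v1"],
                "arm": ["drug", "drug", "vehicle", "vehicle"],
                "day": [0, 28, 0, 28],
                "volume_mm3": [100, 100, 100, 200],
            }
        )
        assert arm_volume_ratio(rec, "drug", "vehicle", 28) == pytest.approx(0.5)
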