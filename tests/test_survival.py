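"""Survival statistics against hand calculations and independent oracles
(lifelines, scikit-survival, scipy)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy import stats

from tallsurv.survival import (
    ContingencyTable2x2,
    SurvivalData,
    compare_clinical_covariates,
    cox_score_test,
    cox_univariate,
    fisher_exact_2x2,
    km_estimate,
    logrank_test,
    screen_features,
    time_dependent_auc,
)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate(SurvivalData([1, 2, 3], [1, 0, 1]))
        np.testing.assert_allclose(km.times, [1, 3])
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])
        # S stays 2/3 across the censored time 2
        assert km.survival_at(2.5) == pytest.approx(2 / 3)

    def test_all_censored_stays_at_one(self):
        km = km_estimate(SurvivalData([5, 10, 15], [0, 0, 0]))
        assert len(km.times) == 0 and km.survival_at(20) == 1.0

    def test_single_event_drops_to_zero(self):
        km = km_estimate(SurvivalData([7.0], [1]))
        assert km.survival_at(7.0) == 0.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, 50) + 0.1
        km = km_estimate(SurvivalData(t, np.ones(50)))
        grid = np.linspace(0.1, t.max(), 37)
        empirical = (t[None, :] > grid[:, None]).mean(axis=1)
        np.testing.assert_allclose(km.survival_at(grid), empirical, atol=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(10, 60).round(0) + 1
        e = (rng.uniform(size=60) < 0.7).astype(float)
        km = km_estimate(SurvivalData(t, e))
        kmf = KaplanMeierFitter().fit(t, e)
        np.testing.assert_allclose(
            km.survival_at(km.times), kmf.survival_function_at_times(km.times).to_numpy(), atol=1e-10
        )


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    times=st_.lists(st_.floats(0.1, 1e4), min_size=1, max_size=40),
    event_bits=st_.lists(st_.booleans(), min_size=40, max_size=40),
)
def test_km_curve_is_a_valid_survival_function(times, event_bits):
    """For any censoring pattern, S is non-increasing and within [0, 1]."""
    events = np.array(event_bits[: len(times)], dtype=float)
    km = km_estimate(SurvivalData(np.array(times), events))
    assert np.all(km.survival <= 1.0 + 1e-12) and np.all(km.survival >= -1e-12)
    assert np.all(np.diff(km.survival) <= 1e-12)
    assert np.all(np.diff(km.times) > 0)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(cells=st_.tuples(*[st_.integers(0, 25)] * 4))
def test_fisher_transpose_and_row_swap_symmetry(cells):
    a, b, c, d = cells
    if a + b + c + d == 0 or (a + b == 0) or (c + d == 0):
        return
    p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
    assert 0 < p <= 1
    assert p == pytest.approx(fisher_exact_2x2(ContingencyTable2x2(c, d, a, b)), rel=1e-12)
    assert p == pytest.approx(fisher_exact_2x2(ContingencyTable2x2(b, a, d, c)), rel=1e-12)


class TestLogrank:
    def test_hand_example(self):
        s = SurvivalData([1, 2, 3, 4, 5, 6], [1] * 6)
        chi2, p = logrank_test(s, np.array([0, 0, 0, 1, 1, 1]))
        assert chi2 == pytest.approx(5.052, abs=5e-3)
        assert p == pytest.approx(0.025, abs=1e-3)

    def test_identical_groups_null(self):
        s = SurvivalData([1, 2, 3, 1, 2, 3], [1, 0, 1, 1, 0, 1])
        chi2, p = logrank_test(s, np.array([0, 0, 0, 1, 1, 1]))
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == 1.0

    def test_label_swap_symmetry(self, rng):
        t = rng.exponential(5, 40) + 0.1
        e = (rng.uniform(size=40) < 0.8).astype(float)
        g = (rng.uniform(size=40) < 0.5).astype(int)
        s = SurvivalData(t, e)
        assert logrank_test(s, g)[0] == pytest.approx(logrank_test(s, 1 - g)[0], rel=1e-12)

    def test_matches_lifelines_with_ties(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        t = rng.exponential(30, 70).round(0) + 1  # rounding creates ties
        e = (rng.uniform(size=70) < 0.7).astype(float)
        g = (rng.uniform(size=70) < 0.4).astype(int)
        chi2, p = logrank_test(SurvivalData(t, e), g)
        ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)


class TestCoxUnivariate:
    def test_score_test_equals_logrank_without_ties(self, rng):
        # analytical identity for a binary covariate, checked on random instances
        for trial in range(50):
            n = int(rng.integers(12, 40))
            t = rng.exponential(10, n) + rng.uniform(0, 1e-3, n)  # no ties
            e = (rng.uniform(size=n) < 0.75).astype(float)
            x = (rng.uniform(size=n) < 0.5).astype(float)
            if e[x == 0].sum() == 0 or e[x == 1].sum() == 0:
                continue
            s = SurvivalData(t, e)
            fit = cox_univariate(s, x)
            chi2, _ = logrank_test(s, x)
            assert fit.score_stat == pytest.approx(chi2, rel=1e-6)

    def test_matches_lifelines_coefficient(self, rng):
        from lifelines import CoxPHFitter

        t = rng.exponential(100, 80).round(1) + 1  # tied times exercise Efron handling
        e = (rng.uniform(size=80) < 0.7).astype(float)
        x = rng.normal(size=80)
        fit = cox_univariate(SurvivalData(t, e), x)
        cph = CoxPHFitter().fit(pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-4)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_negating_covariate_negates_beta(self, rng):
        t = rng.exponential(10, 50) + 0.01
        e = np.ones(50)
        x = rng.normal(size=50)
        s = SurvivalData(t, e)
        assert cox_univariate(s, -x).beta == pytest.approx(-cox_univariate(s, x).beta, rel=1e-8)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_univariate(SurvivalData([1, 2, 3], [1, 1, 1]), np.ones(3))

    def test_null_covariate_p_uniform(self, rng):
        # score-test p under independence: ~5% rejections at alpha=0.05
        n, reps = 60, 500
        rejections = 0
        for _ in range(reps):
            t = rng.exponential(10, n) + 0.01
            e = (rng.uniform(size=n) < 0.7).astype(float)
            x = rng.normal(size=n)
            p = cox_score_test(SurvivalData(t, e), x[:, None])[0]
            rejections += p < 0.05
        assert 0.025 <= rejections / reps <= 0.075


class TestScreenFeatures:
    def test_strong_signal_selected(self, rng):
        n = 100
        t = rng.exponential(10, n) + 0.01
        s = SurvivalData(t, np.ones(n))
        feats = np.column_stack([-np.log(t), rng.normal(size=n)])
        idx = screen_features(feats, s)
        assert 0 in idx

    def test_alpha_zero_selects_nothing(self, rng):
        s = SurvivalData(rng.exponential(10, 30) + 0.1, np.ones(30))
        assert len(screen_features(rng.normal(size=(30, 5)), s, alpha=0)) == 0

    def test_constant_feature_skipped_with_warning(self, rng):
        s = SurvivalData(rng.exponential(10, 30) + 0.1, np.ones(30))
        feats = np.column_stack([np.ones(30), rng.normal(size=30)])
        with pytest.warns(UserWarning, match="constant"):
            idx = screen_features(feats, s, alpha=1.0)
        assert list(idx) == [1]


class TestTimeDependentAUC:
    def test_perfect_score_and_affine_invariance(self, rng):
        t = rng.exponential(10, 50) + 0.1
        s = SurvivalData(t, np.ones(50))
        h = float(np.median(t))
        assert time_dependent_auc(-t, s, h).auc == 1.0
        score = rng.normal(size=50)
        a1 = time_dependent_auc(score, s, h).auc
        a2 = time_dependent_auc(3.5 * score - 2, s, h).auc
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_random_score_near_half(self, rng):
        n = 1000
        t = rng.exponential(10, n) + 0.1
        e = (rng.uniform(size=n) < 0.7).astype(float)
        res = time_dependent_auc(rng.normal(size=n), SurvivalData(t, e), float(np.median(t)))
        assert 0.45 <= res.auc <= 0.55

    def test_matches_sksurv_under_censoring(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        n = 250
        t = rng.exponential(100, n) + 1
        e = (rng.uniform(size=n) < 0.7).astype(float)
        score = -t / 50 + rng.normal(size=n)
        y = Surv.from_arrays(e.astype(bool), t)
        for h in (60.0, 140.0):
            ours = time_dependent_auc(score, SurvivalData(t, e), h).auc
            ref, _ = cumulative_dynamic_auc(y, y, score, [h])
            assert ours == pytest.approx(ref[0], rel=1e-10)

    def test_errors_without_cases_or_controls(self):
        s = SurvivalData([10, 20, 30], [0, 0, 1])
        with pytest.raises(ValueError, match="cases"):
            time_dependent_auc(np.array([1.0, 2.0, 3.0]), s, 15.0)


class TestFisherExact:
    def test_printed_gender_table(self):
        # K0 2F/10M vs K1 3F/5M; exact enumeration = 43745/125970
        p = fisher_exact_2x2(ContingencyTable2x2(2, 10, 3, 5))
        assert p == pytest.approx(43745 / 125970, rel=1e-12)
        assert round(p, 1) == 0.3

    def test_printed_hsct_table(self):
        assert fisher_exact_2x2(ContingencyTable2x2(7, 5, 4, 4)) == pytest.approx(1.0)

    def test_symmetric_table(self):
        assert fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5)) == 1.0

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if a + b + c + d == 0:
                continue
            ours = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            _, ref = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fisher_exact_2x2(ContingencyTable2x2(0, 0, 0, 0))

    def test_enumeration_masses_sum_to_one(self, rng):
        # p at the observed table's own probability threshold covers the whole
        # support when the observed table is the most probable one
        import math

        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(1, 10, size=4))
            r1, c1, n = a + b, a + c, a + b + c + d
            lo, hi = max(0, r1 + c1 - n), min(r1, c1)
            total = sum(math.comb(c1, k) * math.comb(n - c1, r1 - k) for k in range(lo, hi + 1))
            assert total == math.comb(n, r1)


class TestCompareClinicalCovariates:
    def _cohort(self, rng, n=20):
        from tallsurv.io_preprocess import ClinicalTable

        df = pd.DataFrame(
            {
                "time_days": rng.exponential(300, n) + 1,
                "event": (rng.uniform(size=n) < 0.6).astype(int),
                "gender": np.r_[["Female"] * 5, ["Male"] * (n - 5)],
                "age": rng.normal(30, 8, n).round(1),
            },
            index=[f"S{i}" for i in range(n)],
        )
        return ClinicalTable(df)

    def test_gender_table_reproduces_printed_p(self, rng):
        from tallsurv.io_preprocess import ClinicalTable
        from tallsurv.subtyping import SubgroupLabeling

        # construct the printed 2x2: K0 2F/10M, K1 3F/5M
        gender = ["Female"] * 2 + ["Male"] * 10 + ["Female"] * 3 + ["Male"] * 5
        labels = [0] * 12 + [1] * 8
        ids = [f"S{i}" for i in range(20)]
        clin = ClinicalTable(
            pd.DataFrame(
                {"time_days": np.arange(1.0, 21.0), "event": [1] * 20, "gender": gender}, index=ids
            )
        )
        res = compare_clinical_covariates(clin, SubgroupLabeling(ids, np.array(labels)))
        gender_res = next(r for r in res if r.covariate == "gender")
        assert round(gender_res.p_value, 1) == 0.3

    def test_identical_continuous_covariate(self, rng):
        from tallsurv.io_preprocess import ClinicalTable
        from tallsurv.subtyping import SubgroupLabeling

        ids = [f"S{i}" for i in range(10)]
        clin = ClinicalTable(
            pd.DataFrame(
                {"time_days": np.arange(1.0, 11.0), "event": [1] * 10, "age": [30.0] * 10}, index=ids
            )
        )
        res = compare_clinical_covariates(clin, SubgroupLabeling(ids, np.array([0] * 5 + [1] * 5)))
        assert res[0].p_value == pytest.approx(1.0)

    def test_covariate_missing_in_one_group_untestable(self, rng):
        from tallsurv.io_preprocess import ClinicalTable
        from tallsurv.subtyping import SubgroupLabeling

        ids = [f"S{i}" for i in range(8)]
        age = [30.0, 31.0, 32.0, 33.0, None, None, None, None]
        clin = ClinicalTable(
            pd.DataFrame({"time_days": np.arange(1.0, 9.0), "event": [1] * 8, "age": age}, index=ids)
        )
        res = compare_clinical_covariates(clin, SubgroupLabeling(ids, np.array([0] * 4 + [1] * 4)))
        assert res[0].p_value is None and "untestable" in res[0].detail

    def test_null_covariate_rejection_rate(self, rng):
        from tallsurv.io_preprocess import ClinicalTable
        from tallsurv.subtyping import SubgroupLabeling

        n, reps, rej = 40, 500, 0
        ids = [f"S{i}" for i in range(n)]
        labels = SubgroupLabeling(ids, np.r_[np.zeros(20, int), np.ones(20, int)])
        for _ in range(reps):
            clin = ClinicalTable(
                pd.DataFrame(
                    {"time_days": np.ones(n), "event": np.ones(n, int), "wbc": rng.normal(size=n)},
                    index=ids,
                )
            )
            res = compare_clinical_covariates(clin, labels)
            rej += res[0].p_value < 0.05
        assert 0.025 <= rej / reps <= 0.075
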