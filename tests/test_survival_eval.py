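"""Survival metrics against brute-force oracles and lifelines."""

import numpy as np
import pytest
from lifelines.statistics import logrank_test as ll_logrank
from lifelines.utils import concordance_index as ll_cindex
from scipy import stats

from cychyp import (CychypError, binary_metrics_at_horizon, compare_paired,
                    concordance_index, cox_hr, km_estimate, logrank_test,
                    pool_estimates)
from conftest import random_survival_data


# ---------------------------------------------------------------- oracles
def km_oracle(time, event):
    """Explicit product over event times."""
    out = []
    s = 1.0
    for et in sorted(set(t for t, e in zip(time, event) if e)):
        n = sum(t >= et for t in time)
        d = sum(t == et and e for t, e in zip(time, event))
        s *= 1 - d / n
        out.append((et, s))
    return out


def logrank_oracle(group, time, event):
    """Risk-set-by-risk-set O-E and hypergeometric variance."""
    o_e, v = 0.0, 0.0
    for et in sorted(set(t for t, e in zip(time, event) if e)):
        n = sum(t >= et for t in time)
        n1 = sum(t >= et and g for t, g in zip(time, group))
        d = sum(t == et and e for t, e in zip(time, event))
        d1 = sum(t == et and e and g
                 for t, e, g in zip(time, event, group))
        o_e += d1 - n1 * d / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_e ** 2 / v
    return chi2, float(stats.chi2.sf(chi2, 1))


def cindex_oracle(score, time, event):
    """Exhaustive pair enumeration with Harrell's usability rules."""
    num = den = 0.0
    n = len(score)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if score[i] > score[j]:
                    num += 1
                elif score[i] == score[j]:
                    num += 0.5
    return num / den


class TestKaplanMeier:
    def test_no_events_is_flat_at_one(self):
        curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert curve.times.size == 0  # no steps: survival stays 1

    def test_three_events_product_limit_by_hand(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_matches_oracle_on_random_data(self):
        rng = np.random.default_rng(10)
        for _ in range(60):
            _, time, event = random_survival_data(rng)
            curve = km_estimate(time, event)
            oracle = km_oracle(time, event)
            np.testing.assert_allclose(curve.survival,
                                       [s for _, s in oracle], atol=1e-12)

    def test_survival_is_monotone_nonincreasing(self):
        rng = np.random.default_rng(11)
        _, time, event = random_survival_data(rng, n=80)
        curve = km_estimate(time, event)
        assert (np.diff(curve.survival) <= 1e-15).all()


class TestLogrank:
    def test_hand_worked_six_patient_example(self):
        group = [0, 0, 0, 1, 1, 1]
        time = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        event = [1, 1, 1, 1, 1, 1]
        chi2, p = logrank_test(group, time, event)
        chi2_o, p_o = logrank_oracle(group, time, event)
        assert chi2 == pytest.approx(chi2_o, abs=1e-12)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_matches_oracle_and_lifelines_on_random_data(self):
        rng = np.random.default_rng(12)
        for _ in range(60):
            _, time, event = random_survival_data(rng)
            group = rng.integers(0, 2, len(time))
            if group.sum() in (0, len(group)) or event.sum() == 0:
                continue
            chi2, p = logrank_test(group, time, event)
            chi2_o, _ = logrank_oracle(group, time, event)
            assert chi2 == pytest.approx(chi2_o, abs=1e-10)
            ll = ll_logrank(time[group == 0], time[group == 1],
                            event[group == 0], event[group == 1])
            assert chi2 == pytest.approx(ll.test_statistic, rel=1e-6)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(13)
        _, time, event = random_survival_data(rng)
        group = rng.integers(0, 2, len(time))
        chi2_a, p_a = logrank_test(group, time, event)
        chi2_b, p_b = logrank_test(1 - group, time, event)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-12)
        assert p_a == pytest.approx(p_b, rel=1e-12)

    def test_type_one_error_is_calibrated(self):
        rng = np.random.default_rng(14)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            time = rng.exponential(5, 40)
            event = (rng.random(40) > 0.3).astype(int)
            group = rng.integers(0, 2, 40)
            if group.sum() in (0, 40) or event.sum() == 0:
                continue
            if logrank_test(group, time, event)[1] < 0.05:
                rejections += 1
        assert abs(rejections / n_sim - 0.05) < 0.012

    def test_single_group_raises(self):
        with pytest.raises(CychypError):
            logrank_test([1, 1, 1], [1.0, 2.0, 3.0], [1, 1, 1])


class TestCoxHR:
    def test_reciprocity(self):
        rng = np.random.default_rng(15)
        _, time, event = random_survival_data(rng, n=60)
        group = rng.integers(0, 2, 60)
        hr_ab = cox_hr(group, time, event)[0]
        hr_ba = cox_hr(1 - group, time, event)[0]
        assert hr_ab == pytest.approx(1 / hr_ba, rel=1e-5)

    def test_null_groups_give_unit_hr(self):
        rng = np.random.default_rng(16)
        time = rng.exponential(5, 500)
        event = np.ones(500, dtype=int)
        group = rng.integers(0, 2, 500)
        hr, (lo, hi), _ = cox_hr(group, time, event)
        assert lo < 1 < hi

    def test_rate_ratio_two_recovered(self):
        rng = np.random.default_rng(17)
        group = np.repeat([0, 1], 1000)
        time = np.concatenate([rng.exponential(1.0, 1000),
                               rng.exponential(0.5, 1000)])
        event = np.ones(2000, dtype=int)
        hr, _, p = cox_hr(group, time, event)
        assert 1.8 < hr < 2.2 and p < 1e-10

    def test_monotone_likelihood_warns(self):
        with pytest.warns(UserWarning, match="monotone"):
            hr, (lo, hi), p = cox_hr([0, 0, 1, 1],
                                     [1.0, 2.0, 8.0, 9.0], [1, 1, 0, 0])
        assert hi == np.inf


class TestConcordance:
    def test_perfect_ordering_gives_one(self):
        c, _ = concordance_index([4, 3, 2, 1], [1.0, 2.0, 3.0, 4.0],
                                 [1, 1, 1, 1])
        assert c == 1.0

    def test_reversal_complement_on_tie_free_data(self):
        rng = np.random.default_rng(18)
        score = rng.normal(size=50)  # continuous: no score ties
        time = rng.exponential(5, 50)
        event = (rng.random(50) > 0.3).astype(int)
        c_fwd, _ = concordance_index(score, time, event)
        c_rev, _ = concordance_index(-score, time, event)
        assert c_fwd + c_rev == pytest.approx(1.0, abs=1e-12)

    def test_matches_oracle_and_lifelines_on_random_data(self):
        rng = np.random.default_rng(19)
        for _ in range(60):
            score, time, event = random_survival_data(rng, n=30)
            if event.sum() == 0:
                continue
            c, se = concordance_index(score, time, event)
            assert c == pytest.approx(cindex_oracle(score, time, event),
                                      abs=1e-12)
            assert se > 0

    def test_matches_lifelines_on_tie_free_data(self):
        # tied event times are treated differently by lifelines' estimator,
        # so the cross-check uses continuous times and scores
        rng = np.random.default_rng(23)
        for _ in range(20):
            score = rng.normal(size=40)
            time = rng.exponential(5, 40)
            event = (rng.random(40) > 0.3).astype(int)
            if event.sum() == 0:
                continue
            c, _ = concordance_index(score, time, event)
            assert c == pytest.approx(ll_cindex(time, -score, event),
                                      abs=1e-12)

    def test_no_usable_pairs_raises(self):
        with pytest.raises(CychypError):
            concordance_index([1.0, 2.0], [5.0, 5.0], [0, 0])


class TestBinaryMetrics:
    def test_bcr_is_mean_of_sensitivity_and_specificity(self):
        # 5 cases (4 high), 5 controls (2 high): sens .8, spec .6, BCR .7
        group = [1, 1, 1, 1, 0, 1, 1, 0, 0, 0]
        time = [1.0] * 5 + [9.0] * 5
        event = [1] * 5 + [0] * 5
        sens, spec, bcr, _ = binary_metrics_at_horizon(group, time, event, 5.0)
        assert (sens, spec, bcr) == (0.8, 0.6, pytest.approx(0.7))

    def test_all_high_risk_gives_half_bcr(self):
        sens, spec, bcr, _ = binary_metrics_at_horizon(
            [1, 1, 1, 1], [1.0, 2.0, 9.0, 9.0], [1, 1, 0, 0], 5.0)
        assert (sens, spec, bcr) == (1.0, 0.0, 0.5)

    def test_censored_before_horizon_excluded(self):
        rng = np.random.default_rng(20)
        for _ in range(50):
            score, time, event = random_survival_data(rng)
            group = (score > 0).astype(int)
            case = (event == 1) & (time <= 5.0)
            ctrl = (time >= 5.0) & ~case
            if case.sum() == 0 or ctrl.sum() == 0:
                continue
            sens, spec, bcr, _ = binary_metrics_at_horizon(group, time,
                                                           event, 5.0)
            # confusion-matrix brute force
            assert sens == pytest.approx(group[case].mean())
            assert spec == pytest.approx(1 - group[ctrl].mean())
            assert bcr == pytest.approx((sens + spec) / 2)

    def test_no_cases_raises(self):
        with pytest.raises(CychypError):
            binary_metrics_at_horizon([1, 0], [9.0, 9.0], [0, 0], 5.0)


class TestPooling:
    def test_single_cohort_identity(self):
        est, se, _ = pool_estimates([(0.7, 0.1)], scale="c-index")
        assert (est, se) == (0.7, 0.1)

    def test_two_equal_estimates_halve_variance(self):
        est, se, _ = pool_estimates([(0.6, 0.2), (0.6, 0.2)], scale="BCR")
        assert est == pytest.approx(0.6)
        assert se == pytest.approx(0.2 / np.sqrt(2))

    def test_matches_brute_force_weighted_mean(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            est = rng.normal(size=5)
            se = rng.uniform(0.05, 0.5, size=5)
            pooled, _, _ = pool_estimates(list(zip(est, se)), scale="log-HR")
            w = 1 / se ** 2
            assert pooled == pytest.approx(np.sum(w * est) / np.sum(w))

    def test_pooled_log_hr_within_cohort_range(self):
        rng = np.random.default_rng(22)
        est = rng.normal(size=6)
        se = rng.uniform(0.1, 0.4, size=6)
        pooled, _, _ = pool_estimates(list(zip(est, se)))
        assert est.min() <= pooled <= est.max()


class TestComparePaired:
    @staticmethod
    def _logrank_metric(time, event):
        def metric(groups, idx):
            chi2, p = logrank_test(groups.astype(int), time[idx], event[idx])
            return -np.log10(max(p, 1e-300))
        return metric

    def test_identical_stratifications_give_p_one(self, planted_cohorts):
        _, _, valid, _ = planted_cohorts
        g = valid.clinical["grade"].to_numpy() >= 2
        with pytest.warns(UserWarning, match="degenerate"):
            p = compare_paired(self._logrank_metric(valid.time, valid.event),
                               g, g, valid.time, valid.event, n_boot=50)
        assert p == 1.0

    def test_symmetry_under_swap(self, planted_cohorts):
        sig, _, valid, _ = planted_cohorts
        mean_sig = valid.expr.values.loc[sig.probeset_ids].mean(axis=0)
        a = (mean_sig > mean_sig.median()).to_numpy()
        b = valid.clinical["grade"].to_numpy() >= 2
        metric = self._logrank_metric(valid.time, valid.event)
        p_ab = compare_paired(metric, a, b, valid.time, valid.event,
                              n_boot=100, seed=3)
        p_ba = compare_paired(metric, b, a, valid.time, valid.event,
                              n_boot=100, seed=3)
        assert p_ab == pytest.approx(p_ba)

    def test_informative_beats_random_stratification(self):
        from cychyp import gen_cohort
        significant = 0
        for seed in range(3):
            cohort, truth = gen_cohort(600, ["A"], hr_per_sd=2.0,
                                       censor_rate=0.3, seed=300 + seed)
            rng = np.random.default_rng(seed)
            informative = truth.latent_activity > 0
            random_strat = rng.random(600) > 0.5
            metric = self._logrank_metric(cohort.time, cohort.event)
            p = compare_paired(metric, informative, random_strat,
                               cohort.time, cohort.event, n_boot=200,
                               seed=seed)
            significant += p < 0.05
        assert significant == 3
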