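import numpy as np
import pytest
from lifelines import AalenJohansenFitter, CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from cbfmrd.survival import (cif_estimate, cox_univariate, curve_at, gray_test,
                             km_estimate, logrank_test)


def _competing_data(seed, n, hr_cause1=1.0):
    """Two-group competing-risks draw used across the Gray-test checks."""
    rng = np.random.default_rng(seed)
    g = np.repeat([0, 1], n // 2)
    t1 = rng.exponential(1 / np.where(g == 1, 0.3 * hr_cause1, 0.3))
    t2 = rng.exponential(1 / 0.15, n)
    cens = rng.uniform(0.5, 6, n)
    t = np.round(np.minimum(np.minimum(t1, t2), cens), 6)
    et = np.where(t == np.round(cens, 6), 0, np.where(t1 <= t2, 1, 2))
    return t, et, g


class TestKaplanMeier:
    def test_hand_product_limit(self):
        c = km_estimate([1, 2, 3, 4], [1, 1, 0, 1])
        assert np.allclose(c.survival, [0.75, 0.50, 0.50, 0.0])
        assert curve_at(c, 2.5) == 0.50
        assert curve_at(c, 0.0) == 1.0
        assert curve_at(c, 99.0) == 0.0  # carry last value forward

    def test_no_events_survival_stays_one(self):
        c = km_estimate([1, 2, 3], [0, 0, 0])
        assert np.all(c.survival == 1.0)

    def test_reduces_to_ecdf_without_censoring(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(1, 50)
        c = km_estimate(t, np.ones(50, dtype=int))
        for tt in c.times:
            assert curve_at(c, tt) == pytest.approx(np.mean(t > tt))

    def test_matches_lifelines_to_1e10(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(2, 120)
        e = (rng.random(120) < 0.6).astype(int)
        mine = km_estimate(t, e)
        ref = KaplanMeierFitter().fit(t, e)
        assert np.max(np.abs(
            ref.survival_function_at_times(mine.times).values - mine.survival
        )) < 1e-10

    def test_greenwood_se_monotone_from_zero(self):
        c = km_estimate([1, 2, 3, 4], [1, 1, 0, 1])
        assert c.se[0] > 0
        assert np.all(np.diff(c.se[:2]) >= 0)

    def test_empty_and_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            km_estimate([-1.0], [1])


class TestCIF:
    def test_hand_aalen_johansen(self):
        c = cif_estimate([1, 2, 3], [1, 2, 0])
        assert curve_at(c, 1, cause=1) == pytest.approx(1 / 3)
        assert curve_at(c, 5, cause=1) == pytest.approx(1 / 3)
        assert curve_at(c, 2, cause=2) == pytest.approx(1 / 3)  # (2/3) * (1/2)
        assert curve_at(c, 0.5, cause=1) == 0.0

    def test_single_cause_equals_one_minus_km(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1, 60)
        e = (rng.random(60) < 0.7).astype(int)
        cif = cif_estimate(t, e)
        km = km_estimate(t, e)
        assert np.allclose(cif.cif[1], 1.0 - km.survival, atol=1e-12)
        assert np.all(cif.cif[2] == 0.0)

    def test_all_censored_cifs_zero(self):
        c = cif_estimate([1, 2, 3], [0, 0, 0])
        assert np.all(c.cif[1] == 0.0) and np.all(c.cif[2] == 0.0)

    def test_matches_lifelines_to_1e10(self):
        t, et, _ = _competing_data(9, 100)
        mine = cif_estimate(t, et)
        for cause in (1, 2):
            aj = AalenJohansenFitter(calculate_variance=False).fit(
                t, et, event_of_interest=cause)
            grid = aj.cumulative_density_.index.values
            ref = aj.cumulative_density_.values.ravel()
            got = np.array([curve_at(mine, u, cause=cause) for u in grid])
            assert np.max(np.abs(ref - got)) < 1e-10

    def test_cif_sum_bounded_by_one_minus_survival(self):
        t, et, _ = _competing_data(4, 150)
        cif = cif_estimate(t, et)
        km = km_estimate(t, (et > 0).astype(int))
        total = cif.cif[1] + cif.cif[2]
        assert np.all(total <= 1.0 - km.survival + 1e-10)
        # equality holds at event times
        assert np.allclose(total, 1.0 - km.survival, atol=1e-10)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 0, 1, 1, 1, 0, 1, 1]
        g = [0] * 4 + [1] * 4
        r = logrank_test(t, e, g)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_strong_separation_exceeds_threshold(self):
        t = [1, 2, 3, 10, 10, 10]
        e = [1, 1, 1, 0, 0, 0]
        g = [0, 0, 0, 1, 1, 1]
        assert logrank_test(t, e, g).statistic > 3.84

    def test_matches_lifelines_k_groups(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(2, 150)
        e = (rng.random(150) < 0.7).astype(int)
        g = rng.integers(0, 3, 150)
        mine = logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.df == 2

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(77)
        rej = 0
        reps = 500
        for _ in range(reps):
            t = rng.exponential(2, 100)
            e = (rng.random(100) < 0.8).astype(int)
            g = np.repeat([0, 1], 50)
            if logrank_test(t, e, g).p_value < 0.05:
                rej += 1
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < 3 * se

    def test_invariant_to_time_rescaling(self):
        t, et, g = _competing_data(6, 100)
        e = (et > 0).astype(int)
        a = logrank_test(t, e, g)
        b = logrank_test(t * 123.4, e, g)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestGray:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        et = [1, 2, 0, 1, 1, 2, 0, 1]
        g = [0] * 4 + [1] * 4
        r = gray_test(t, et, g)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_reduces_to_logrank_without_competing_events(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(2, 80)
        e = (rng.random(80) < 0.7).astype(int)
        g = np.repeat([0, 1], 40)
        assert gray_test(t, e, g).statistic == pytest.approx(
            logrank_test(t, e, g).statistic, rel=1e-12)

    @pytest.mark.parametrize("seed,n,ref_stat,ref_p", [
        (101, 80, 1.9849618637, 0.1588686592),
        (202, 120, 1.5966519389, 0.2063783259),
    ])
    def test_close_to_reference_implementation(self, seed, n, ref_stat, ref_p):
        """Frozen values computed with cmprsk::cuminc (R) on the same data."""
        t, et, g = _competing_data(seed, n, hr_cause1=1.5)
        r = gray_test(t, et, g)
        assert r.statistic == pytest.approx(ref_stat, rel=0.05)
        assert r.p_value == pytest.approx(ref_p, abs=0.01)

    def test_agrees_with_permutation_null_no_competing(self):
        """With no competing events the chi-square p matches a group-label
        permutation null of the same statistic on a small dataset."""
        rng = np.random.default_rng(55)
        t = rng.exponential(2, 40)
        e = (rng.random(40) < 0.75).astype(int)
        g = np.repeat([0, 1], 20)
        obs = gray_test(t, e, g)
        perm_stats = np.empty(2000)
        for i in range(2000):
            gp = rng.permutation(g)
            perm_stats[i] = gray_test(t, e, gp).statistic
        p_perm = float(np.mean(perm_stats >= obs.statistic))
        mc_se = np.sqrt(p_perm * (1 - p_perm) / 2000)
        assert abs(obs.p_value - p_perm) < 3 * mc_se + 0.02

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(99)
        rej = 0
        reps = 500
        for _ in range(reps):
            n = 150
            g = np.repeat([0, 1], n // 2)
            t1 = rng.exponential(1 / 0.3, n)
            t2 = rng.exponential(1 / 0.15, n)
            cens = rng.uniform(0.5, 6, n)
            t = np.minimum(np.minimum(t1, t2), cens)
            et = np.where(t == cens, 0, np.where(t1 <= t2, 1, 2))
            if gray_test(t, et, g).p_value < 0.05:
                rej += 1
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < 3 * se

    def test_invariant_to_time_rescaling(self):
        t, et, g = _competing_data(13, 90)
        a = gray_test(t, et, g)
        b = gray_test(t * 42.0, et, g)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_requires_cause_events(self):
        with pytest.raises(ValueError):
            gray_test([1, 2], [2, 0], [0, 1])


class TestCox:
    def test_null_covariate_gives_hr_near_one(self):
        rng = np.random.default_rng(21)
        n = 400
        t = rng.exponential(2, n)
        e = (rng.random(n) < 0.8).astype(int)
        x = rng.normal(size=n)
        fit = cox_univariate(t, e, x)
        assert fit.converged
        assert abs(fit.log_hr) < 3 * fit.se

    def test_recovers_true_hazard_ratio_two(self):
        rng = np.random.default_rng(31)
        n = 500
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1 / (0.2 * np.exp(np.log(2) * x)))
        cens = rng.uniform(0, 10, n)
        e = (t <= cens).astype(int)
        tt = np.minimum(t, cens)
        fit = cox_univariate(tt, e, x)
        assert fit.converged
        assert abs(fit.log_hr - np.log(2)) < 3 * fit.se
        assert fit.ci95[0] < fit.hr < fit.ci95[1]

    def test_matches_lifelines(self):
        import pandas as pd
        rng = np.random.default_rng(41)
        n = 150
        t = rng.exponential(2, n)
        e = (rng.random(n) < 0.7).astype(int)
        x = rng.normal(size=n)
        fit = cox_univariate(t, e, x)
        ref = CoxPHFitter().fit(pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
        assert fit.log_hr == pytest.approx(ref.params_["x"], abs=1e-4)
        assert fit.se == pytest.approx(ref.standard_errors_["x"], abs=1e-4)

    def test_monotone_separation_flagged_not_crashed(self):
        # all group-B times exceed all group-A event times
        t = [1, 2, 3, 10, 11, 12]
        e = [1, 1, 1, 1, 1, 1]
        x = [1, 1, 1, 0, 0, 0]
        fit = cox_univariate(t, e, x)
        assert not fit.converged

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_univariate([1, 2, 3], [1, 1, 0], [1, 1, 1])
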