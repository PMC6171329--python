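"""Survival primitives against independent brute-force oracles."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from ezscore.survival import (
    SurvivalData,
    fit_cox_univariate,
    kaplan_meier,
    logrank_test,
    maxstat_cutpoint,
)

from conftest import make_cohort


# ---------------------------------------------------------------- oracles


def km_product_limit(time, event):
    """Explicit product-limit loop: S(t) over distinct event times."""
    times = np.unique(time[event == 1])
    s, out = 1.0, {}
    for t in times:
        n_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        s *= 1.0 - d / n_risk
        out[t] = s
    return out


def logrank_by_hand(time, event, group):
    """Sum (O-E) and hypergeometric V over event times, explicit loop."""
    u = v = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        u += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return u, v


def efron_neg_loglik(beta, x, time, event):
    """Efron partial log-likelihood for a single covariate, explicit loop."""
    ll = 0.0
    eta = beta * x
    for t in np.unique(time[event == 1]):
        tied = (time == t) & (event == 1)
        at_risk = time >= t
        d = tied.sum()
        sum_tied = np.exp(eta[tied]).sum()
        sum_risk = np.exp(eta[at_risk]).sum()
        ll += eta[tied].sum()
        for j in range(d):
            ll -= np.log(sum_risk - j / d * sum_tied)
    return -ll


# ---------------------------------------------------------------- KM


class TestKaplanMeier:
    def test_all_censored_gives_constant_one(self):
        sv = SurvivalData(np.array([1.0, 2, 3]), np.zeros(3, int), np.array(list("abc")))
        km = kaplan_meier(sv)
        assert km.event_times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_two_subject_half(self):
        sv = SurvivalData(np.array([5.0, 10.0]), np.array([1, 0]), np.array(list("ab")))
        km = kaplan_meier(sv)
        assert km.survival_at(5.0) == pytest.approx(0.5)
        assert km.survival_at(4.9) == 1.0

    def test_matches_explicit_product_limit(self):
        _, sv = make_cohort(50, seed=11)
        km = kaplan_meier(sv)
        oracle = km_product_limit(sv.time, sv.event)
        assert km.event_times.size == len(oracle)
        for t, s in oracle.items():
            assert km.survival_at(t) == pytest.approx(s, abs=1e-12)

    def test_invariant_under_sample_reordering(self):
        _, sv = make_cohort(40, seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(sv))
        sv2 = SurvivalData(sv.time[perm], sv.event[perm], sv.sample_id[perm])
        a, b = kaplan_meier(sv), kaplan_meier(sv2)
        np.testing.assert_allclose(a.survival_prob, b.survival_prob)
        np.testing.assert_array_equal(a.event_times, b.event_times)

    def test_monotone_nonincreasing_in_unit_interval(self):
        _, sv = make_cohort(60, seed=5)
        km = kaplan_meier(sv)
        assert np.all(np.diff(km.survival_prob) <= 1e-12)
        assert np.all((km.survival_prob >= 0) & (km.survival_prob <= 1))


# ---------------------------------------------------------------- log-rank


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = np.array([3.0, 6, 9, 12])
        e = np.array([1, 0, 1, 1])
        sv = SurvivalData(
            np.concatenate([t, t]), np.concatenate([e, e]),
            np.array([f"s{i}" for i in range(8)]),
        )
        g = np.repeat([0, 1], 4)
        stat, p = logrank_test(sv, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computation_small(self):
        time = np.array([2.0, 4, 5, 7, 8, 10, 12, 15])
        event = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        group = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        sv = SurvivalData(time, event, np.array([f"s{i}" for i in range(8)]))
        u, v = logrank_by_hand(time, event, group)
        stat, p = logrank_test(sv, group)
        assert stat == pytest.approx(u**2 / v, rel=1e-9)
        assert p == pytest.approx(stats.chi2.sf(u**2 / v, 1), rel=1e-9)

    def test_p_value_matches_permutation_null(self):
        x, sv = make_cohort(30, seed=21)
        group = (x > np.median(x)).astype(int)
        stat, p = logrank_test(sv, group)
        rng = np.random.default_rng(0)
        n_perm, exceed = 5000, 0
        for _ in range(n_perm):
            gp = rng.permutation(group)
            u, v = logrank_by_hand(sv.time, sv.event, gp)
            if u**2 / v >= stat:
                exceed += 1
        p_perm = (exceed + 1) / (n_perm + 1)
        mc_sd = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p - p_perm) < 4 * mc_sd + 0.01

    def test_invariant_under_label_swap(self):
        x, sv = make_cohort(40, seed=2)
        g = (x > np.median(x)).astype(int)
        assert logrank_test(sv, g)[0] == pytest.approx(logrank_test(sv, 1 - g)[0])

    def test_errors(self):
        _, sv = make_cohort(10, seed=0)
        with pytest.raises(ValueError):
            logrank_test(sv, np.zeros(10, int))
        sv0 = SurvivalData(np.arange(1.0, 5), np.zeros(4, int), np.array(list("abcd")))
        with pytest.raises(ValueError):
            logrank_test(sv0, np.array([0, 0, 1, 1]))


# ---------------------------------------------------------------- Cox


class TestCoxUnivariate:
    def test_recovers_planted_binary_hr2(self):
        rng = np.random.default_rng(4)
        n = 1000
        g = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.05 * np.exp(np.log(2) * g)))
        c = rng.uniform(0, 45, n)
        sv = SurvivalData(np.minimum(t, c), (t <= c).astype(int),
                          np.array([f"s{i}" for i in range(n)]))
        fit = fit_cox_univariate(g, sv)
        assert fit.converged
        assert abs(fit.beta - np.log(2)) < 0.15
        assert fit.hazard_ratio == pytest.approx(np.exp(fit.beta))

    def test_null_covariate_small_beta(self):
        x, sv = make_cohort(1000, seed=8, x_dist="normal")
        fit = fit_cox_univariate(x, sv)
        assert abs(fit.beta) < 3 * fit.se + 0.05
        assert fit.p_value > 0.001

    def test_null_p_values_approximately_uniform(self):
        """Across independent replicates the Wald p of a null covariate
        should be roughly uniform (KS test not rejecting at 0.001)."""
        ps = []
        for seed in range(40):
            x, sv = make_cohort(80, seed=100 + seed, x_dist="normal")
            ps.append(fit_cox_univariate(x, sv).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_matches_brute_force_partial_likelihood(self):
        x, sv = make_cohort(20, seed=13, x_dist="normal")
        fit = fit_cox_univariate(x, sv)
        res = minimize_scalar(
            efron_neg_loglik, args=(x, sv.time, sv.event), bounds=(-5, 5),
            method="bounded", options={"xatol": 1e-10},
        )
        assert abs(fit.beta - res.x) < 1e-4

    def test_sign_flip_of_binary_covariate(self):
        rng = np.random.default_rng(9)
        g = rng.integers(0, 2, 200).astype(float)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.8 * g)))
        sv = SurvivalData(t, np.ones(200, int), np.array([f"s{i}" for i in range(200)]))
        assert fit_cox_univariate(g, sv).beta == pytest.approx(
            -fit_cox_univariate(1 - g, sv).beta, rel=1e-6
        )

    def test_errors(self):
        _, sv = make_cohort(20, seed=1)
        with pytest.raises(ValueError):
            fit_cox_univariate(np.ones(20), sv)
        sv0 = SurvivalData(np.arange(1.0, 21), np.zeros(20, int),
                           np.array([f"s{i}" for i in range(20)]))
        with pytest.raises(ValueError):
            fit_cox_univariate(np.arange(20.0), sv0)


# ---------------------------------------------------------------- maxstat


def brute_force_maxstat(x, sv, min_prop=0.10):
    """Exhaustive search: lifelines log-rank chi-square at every midpoint."""
    n = len(sv)
    lo = int(np.ceil(min_prop * n))
    xs = np.sort(np.unique(x))
    best = None
    for a, b in zip(xs[:-1], xs[1:]):
        cut = (a + b) / 2
        g = (x > cut).astype(int)
        if g.sum() < lo or (n - g.sum()) < lo:
            continue
        stat, _ = logrank_test(sv, g)
        if best is None or stat > best[1] + 1e-12:
            best = (cut, stat)
    return best


class TestMaxstat:
    def test_perfect_separation_cut_in_gap(self):
        n = 40
        x = np.concatenate([np.full(20, 50.0), np.full(20, 150.0)])
        time = np.concatenate([np.arange(1.0, 21), np.arange(100.0, 120)])
        event = np.concatenate([np.ones(20, int), np.zeros(20, int)])
        sv = SurvivalData(time, event, np.array([f"s{i}" for i in range(n)]))
        ms = maxstat_cutpoint(x, sv)
        assert 50.0 < ms.cutpoint <= 150.0
        assert ms.n_low == ms.n_high == 20

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_exhaustive_search(self, seed):
        x, sv = make_cohort(60, seed=seed)
        ms = maxstat_cutpoint(x, sv)
        cut, stat = brute_force_maxstat(x, sv)
        assert ms.cutpoint == pytest.approx(cut, rel=1e-12)
        assert ms.chisq == pytest.approx(stat, rel=1e-9)

    def test_chisq_equals_logrank_at_selected_split(self, null_cohort):
        x, sv = null_cohort
        ms = maxstat_cutpoint(x, sv)
        stat, _ = logrank_test(sv, (x > ms.cutpoint).astype(int))
        assert ms.chisq == pytest.approx(stat, rel=1e-9)

    @pytest.mark.parametrize(
        "transform", [np.log, np.sqrt, lambda v: 3 * v + 7, lambda v: v**3]
    )
    def test_invariant_under_monotone_transform(self, null_cohort, transform):
        x, sv = null_cohort
        a = maxstat_cutpoint(x, sv)
        b = maxstat_cutpoint(transform(x), sv)
        assert a.max_statistic == pytest.approx(b.max_statistic, rel=1e-9)
        # transformed cutpoint separates the same samples
        assert np.array_equal(x > a.cutpoint, transform(x) > b.cutpoint)

    def test_min_prop_respected(self, null_cohort):
        x, sv = null_cohort
        ms = maxstat_cutpoint(x, sv, min_prop=0.25)
        frac = ms.n_low / (ms.n_low + ms.n_high)
        assert 0.25 <= frac <= 0.75

    def test_corrected_p_conservative_vs_permutation(self):
        x, sv = make_cohort(50, seed=77)
        approx = maxstat_cutpoint(x, sv, p_method="approx")
        perm = maxstat_cutpoint(x, sv, p_method="permutation", n_perm=2000, seed=5)
        assert approx.p_value >= perm.p_value - 0.03

    def test_no_admissible_cutpoint_raises(self):
        _, sv = make_cohort(20, seed=6)
        with pytest.raises(ValueError):
            maxstat_cutpoint(np.ones(20), sv)
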