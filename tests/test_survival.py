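"""Survival statistics against hand-built oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gepreport.survival import (CoxFitError, CoxRiskModel,
                                KaplanMeierReference, brier_curve,
                                censoring_km, compare_prediction_error,
                                cox_fit, cv_prediction_error,
                                integrated_brier, ipcw_brier, kaplan_meier,
                                logrank_test)

# -- Kaplan-Meier ----------------------------------------------------------


def test_km_all_censored_stays_at_one():
    est = kaplan_meier([5, 6, 7], [0, 0, 0])
    assert est.survival_at(10) == 1.0
    assert not est.median_reached


def test_km_all_events_steps_down():
    est = kaplan_meier([1, 2, 3], [1, 1, 1])
    np.testing.assert_allclose(est.survival, [2 / 3, 1 / 3, 0.0])
    assert est.median == 2.0


def test_km_hand_product_limit_with_censoring():
    # {1 censored, 2 event, 3 event}: S(2) = 1/2, S(3) = 0
    est = kaplan_meier([1, 2, 3], [0, 1, 1])
    assert est.survival_at(2) == pytest.approx(0.5)
    assert est.survival_at(3) == pytest.approx(0.0)
    assert est.survival_at(1.5) == 1.0  # censoring does not drop S


def test_km_no_censoring_equals_empirical_survival(rng):
    times = rng.exponential(10, 40).round(1)
    est = kaplan_meier(times, np.ones(40, int))
    for t in np.quantile(times, [0.1, 0.5, 0.9]):
        assert est.survival_at(t) == pytest.approx(np.mean(times > t))


def test_km_greenwood_matches_hand_formula():
    times = [1, 2, 2, 4, 5]
    events = [1, 1, 0, 1, 0]
    est = kaplan_meier(times, events)
    s, var, cum = 1.0, [], 0.0
    for t, n, d in [(1, 5, 1), (2, 4, 1), (4, 2, 1)]:
        s *= 1 - d / n
        cum += d / (n * (n - d))
        var.append(s**2 * cum)
    np.testing.assert_allclose(est.variance, var)


# -- log-rank --------------------------------------------------------------


def logrank_oracle(times, events, groups):
    """Brute-force hypergeometric accumulation (2 groups, rho = 0)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    g1 = np.unique(groups)[1]
    o_e, v = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at = times >= t
        n, n1 = at.sum(), (at & (groups == g1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == g1)).sum()
        o_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_e**2 / v


def test_identical_groups_statistic_zero_p_one():
    res = logrank_test([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0],
                       ["a", "a", "a", "b", "b", "b"])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_six_subject_hand_oracle():
    t = [1, 2, 3, 4, 5, 6]
    e = [1, 1, 0, 1, 1, 1]
    g = [0, 0, 0, 1, 1, 1]
    res = logrank_test(t, e, g)
    assert res.statistic == pytest.approx(logrank_oracle(t, e, g), abs=1e-9)
    assert res.df == 1
    # p is the chi-square(1) upper tail of the statistic
    from scipy.stats import chi2
    assert res.p_value == pytest.approx(chi2.sf(res.statistic, 1))


def test_logrank_invariant_under_group_relabeling(rng):
    t = rng.exponential(5, 20)
    e = rng.integers(0, 2, 20)
    g = rng.choice(["x", "y"], 20)
    relabel = np.where(g == "x", "y", "x")
    a = logrank_test(t, e, g)
    b = logrank_test(t, e, relabel)
    assert a.statistic == pytest.approx(b.statistic)


def test_logrank_matches_oracle_on_random_small_instances():
    rng = np.random.default_rng(17)
    for _ in range(10):
        t = rng.integers(1, 9, 8).astype(float)
        e = rng.integers(0, 2, 8)
        g = np.array([0, 0, 1, 1] + list(rng.integers(0, 2, 4)))
        if e.sum() == 0:
            continue
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(logrank_oracle(t, e, g),
                                              abs=1e-9)


def test_grho_weighting_changes_statistic():
    t = [1, 2, 3, 4, 5, 6, 7, 8]
    e = [1, 1, 1, 1, 1, 1, 1, 1]
    g = [0, 1, 0, 1, 0, 1, 0, 1]
    assert logrank_test(t, e, g, rho=1.0).statistic != pytest.approx(
        logrank_test(t, e, g, rho=0.0).statistic)


def test_single_group_rejected():
    with pytest.raises(ValueError):
        logrank_test([1, 2], [1, 1], ["a", "a"])


# -- Cox -------------------------------------------------------------------


def test_cox_independent_covariate_hr_near_one():
    df = pd.DataFrame({
        "time": [1, 2, 3, 4, 5, 6, 1, 2, 3, 4, 5, 6],
        "event": [1, 1, 1, 0, 1, 1] * 2,
        "x": [0.0] * 6 + [1.0] * 6,
    })
    fit = cox_fit(df, "time", "event", ["x"])
    assert fit.coef["x"] == pytest.approx(0.0, abs=1e-6)
    assert fit.hazard_ratio["x"] == pytest.approx(1.0, abs=1e-6)


def test_cox_matches_grid_search_partial_likelihood():
    df = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0],
                       "event": [1, 1, 1, 1],
                       "x": [1.0, 0.0, 1.0, 0.0]})

    t = df["time"].to_numpy()
    x = df["x"].to_numpy()

    def partial_ll(b):
        b = np.atleast_1d(np.asarray(b, float))
        theta = np.exp(np.multiply.outer(b, x))  # (grid, subjects)
        risk = t[None, :] >= t[:, None]  # row i: risk set at time i
        return (np.multiply.outer(b, x).sum(axis=1)
                - np.log(theta @ risk.T).sum(axis=1))

    grid = np.linspace(-3, 3, 60001)
    beta_grid = grid[np.argmax(partial_ll(grid))]
    fit = cox_fit(df, "time", "event", ["x"])
    assert fit.coef["x"] == pytest.approx(beta_grid, abs=1e-4)
    assert fit.log_likelihood == pytest.approx(partial_ll(fit.coef["x"])[0],
                                               abs=1e-6)


def test_cox_efron_partial_likelihood_with_ties_matches_oracle():
    """Log-likelihood at the fitted coefficient equals a hand-coded Efron
    partial likelihood on tied data."""
    df = pd.DataFrame({"time": [1.0, 1.0, 2.0, 2.0, 3.0, 4.0],
                       "event": [1, 1, 1, 0, 1, 1],
                       "x": [1.0, 0.0, 1.0, 1.0, 0.0, 1.0]})
    fit = cox_fit(df, "time", "event", ["x"])

    def efron_ll(b):
        t = df["time"].to_numpy()
        e = df["event"].to_numpy()
        x = df["x"].to_numpy()
        theta = np.exp(b * x)
        ll = 0.0
        for tt in np.unique(t[e == 1]):
            dead = (t == tt) & (e == 1)
            risk = t >= tt
            d = dead.sum()
            sum_dead = theta[dead].sum()
            ll += b * x[dead].sum()
            for l in range(d):
                ll -= np.log(theta[risk].sum() - (l / d) * sum_dead)
        return ll

    assert fit.log_likelihood == pytest.approx(efron_ll(fit.coef["x"]),
                                               abs=1e-8)


def test_cox_constant_covariate_is_rank_deficiency_error():
    df = pd.DataFrame({"time": [1.0, 2, 3, 4], "event": [1, 1, 1, 1],
                       "x": [1.0, 1.0, 1.0, 1.0]})
    with pytest.raises(CoxFitError, match="constant"):
        cox_fit(df, "time", "event", ["x"])


def test_cox_no_events_rejected():
    df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
    with pytest.raises(CoxFitError):
        cox_fit(df, "time", "event", ["x"])


# -- IPCW Brier ------------------------------------------------------------


def ipcw_brier_oracle(surv, times, events, grid):
    """Term-by-term brute-force evaluation of the IPCW Brier formula."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    gt, gv = censoring_km(times, events)

    def g_at(t, left=False):
        vals = [v for u, v in zip(gt, gv) if (u < t if left else u <= t)]
        return vals[-1] if vals else 1.0

    out = []
    for j, t in enumerate(grid):
        total = 0.0
        for i in range(len(times)):
            if times[i] <= t and events[i] == 1:
                total += surv[i, j] ** 2 / g_at(times[i], left=True)
            elif times[i] > t:
                total += (1 - surv[i, j]) ** 2 / g_at(t)
        out.append(total / len(times))
    return np.array(out)


def test_constant_half_prediction_no_censoring_is_quarter():
    times = np.array([2.0, 4.0, 6.0, 8.0])
    events = np.ones(4, int)
    grid = np.array([0.0, 3.0, 5.0, 7.0])
    bs = ipcw_brier(np.full((4, 4), 0.5), times, events, grid)
    np.testing.assert_allclose(bs, 0.25)
    assert integrated_brier(grid, bs) == pytest.approx(0.25)


def test_oracle_indicator_predictions_give_zero_error():
    times = np.array([2.0, 4.0, 6.0, 8.0])
    events = np.ones(4, int)
    grid = np.array([1.0, 3.0, 5.0, 7.0])
    surv = np.array([[float(t < ti) for t in grid] for ti in times])
    bs = ipcw_brier(surv, times, events, grid)
    np.testing.assert_allclose(bs, 0.0, atol=1e-12)


def test_ipcw_formula_matches_term_by_term_oracle(rng):
    n = 30
    t_event = rng.exponential(10, n)
    c = rng.exponential(12, n)
    times = np.minimum(t_event, c)
    events = (t_event <= c).astype(int)
    grid = np.array([1.0, 2.5, 5.0, 9.0])
    surv = rng.uniform(0.1, 0.95, size=(n, len(grid)))
    np.testing.assert_allclose(
        ipcw_brier(surv, times, events, grid),
        ipcw_brier_oracle(surv, times, events, grid), atol=1e-12)


def test_brier_bounded_and_grid_truncated_when_g_vanishes(rng):
    times = np.array([1.0, 2.0, 3.0, 4.0])
    events = np.array([1, 1, 1, 0])  # last subject censored at 4
    grid = np.array([0.5, 3.5, 10.0])  # G(t) = 0 beyond the last censoring
    surv = rng.uniform(0, 1, size=(4, 3))
    with pytest.warns(UserWarning, match="truncating"):
        bs = ipcw_brier(surv, times, events, grid)
    assert len(bs) == 2
    assert np.all((bs >= 0) & (bs <= 1))


# -- CV prediction error ---------------------------------------------------


def _toy_cohort(n=160, seed=2):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(20 * np.exp(-0.9 * x))
    c = rng.exponential(40, n)
    return pd.DataFrame({
        "time": np.minimum(t, c), "event": (t <= c).astype(int),
        "risk": x, "noise": rng.integers(0, 2, n).astype(float),
    })


def test_reference_cv_ibs_close_to_full_sample_value():
    df = _toy_cohort()
    models = {"Reference": KaplanMeierReference()}
    cv = cv_prediction_error(models, df, horizon=40, subsample_size=100,
                             n_replicates=20, seed=5)
    full = brier_curve(KaplanMeierReference(), df, df,
                       cv.grid, "time", "event")
    assert cv.curves["Reference"].ibs == pytest.approx(full.ibs, abs=0.02)


def test_identical_models_have_identical_replicate_errors():
    df = _toy_cohort()
    models = {"a": CoxRiskModel(covariates=("risk",)),
              "b": CoxRiskModel(covariates=("risk",))}
    cv = cv_prediction_error(models, df, horizon=40, subsample_size=100,
                             n_replicates=8, seed=3)
    np.testing.assert_allclose(cv.per_replicate_ibs["a"],
                               cv.per_replicate_ibs["b"], atol=1e-12)


def test_cv_reproducible_bit_for_bit_for_fixed_seed():
    df = _toy_cohort()
    models = {"cox": CoxRiskModel(covariates=("risk",)),
              "ref": KaplanMeierReference()}
    a = cv_prediction_error(models, df, horizon=40, subsample_size=100,
                            n_replicates=6, seed=9)
    b = cv_prediction_error(models, df, horizon=40, subsample_size=100,
                            n_replicates=6, seed=9)
    assert a.per_replicate_ibs.equals(b.per_replicate_ibs)
    np.testing.assert_array_equal(a.curves["cox"].brier,
                                  b.curves["cox"].brier)


def test_informative_model_beats_noise_model():
    df = _toy_cohort(n=240, seed=6)
    models = {"true": CoxRiskModel(covariates=("risk",)),
              "noise": CoxRiskModel(covariates=("noise",))}
    cv = cv_prediction_error(models, df, horizon=40, subsample_size=160,
                             n_replicates=15, seed=1)
    assert cv.curves["true"].ibs < cv.curves["noise"].ibs


# -- paired comparison -----------------------------------------------------


def wilcoxon_signflip_oracle(d, alternative="two-sided"):
    """Exact signed-rank null by exhaustive sign-flip enumeration."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [ranks[np.array(bits, bool)].sum()
          for bits in itertools.product([0, 1], repeat=n)]
    ws = np.array(ws)
    if alternative == "two-sided":
        mean = n * (n + 1) / 4
        return np.mean(np.abs(ws - mean) >= abs(w_obs - mean) - 1e-12)
    if alternative == "less":  # a < b, i.e. small W+
        return np.mean(ws <= w_obs + 1e-12)
    return np.mean(ws >= w_obs - 1e-12)


def test_identical_sequences_p_one():
    a = np.array([0.1, 0.2, 0.3])
    assert compare_prediction_error(a, a.copy()) == 1.0


def test_uniform_improvement_is_significant_at_many_replicates(rng):
    b = rng.uniform(0.2, 0.4, 150)
    a = b - 0.01
    assert compare_prediction_error(a, b, alternative="less") < 0.01


def test_small_sample_matches_exact_signflip_enumeration(rng):
    for alternative in ("two-sided", "less"):
        for _ in range(5):
            a = rng.uniform(0.1, 0.3, 9)
            b = a + rng.normal(0, 0.05, 9)
            p = compare_prediction_error(a, b, alternative=alternative)
            assert p == pytest.approx(
                wilcoxon_signflip_oracle(a - b, alternative), abs=1e-9)


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        compare_prediction_error([1.0, 2.0], [1.0])
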