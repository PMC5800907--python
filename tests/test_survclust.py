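import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from _oracles import complete_linkage_oracle, efron_neg_loglik, merges_from_linkage
from accstrat import survclust


def _mat(X, samples=None):
    X = np.asarray(X, dtype=float)
    samples = samples or [f"s{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, index=[f"g{i}" for i in range(X.shape[0])], columns=samples)


# ------------------------------------------------------------ clustering

@pytest.mark.parametrize("n", [3, 5, 8])
def test_complete_linkage_matches_oracle(n, rng):
    for _ in range(10):
        X = rng.normal(size=(n, 4))
        dendro = survclust.hierarchical_cluster(_mat(X.T))
        got = merges_from_linkage(dendro.linkage, n)
        expected = complete_linkage_oracle(X)
        for (ga, gb, gh), (ea, eb, eh) in zip(got, expected):
            assert {ga, gb} == {ea, eb}
            assert gh == pytest.approx(eh)


def test_two_samples_merge_at_euclidean_distance():
    m = _mat([[0.0, 3.0], [0.0, 4.0]])
    dendro = survclust.hierarchical_cluster(m)
    assert dendro.heights[0] == pytest.approx(5.0)


def test_duplicate_sample_merges_at_zero(rng):
    X = rng.normal(size=(6, 4))
    X[:, 1] = X[:, 0]
    dendro = survclust.hierarchical_cluster(_mat(X))
    assert dendro.heights[0] == pytest.approx(0.0)


def test_heights_nondecreasing(rng):
    dendro = survclust.hierarchical_cluster(_mat(rng.normal(size=(10, 12))))
    assert (np.diff(dendro.heights) >= -1e-12).all()


def test_nan_matrix_rejected():
    m = _mat([[1.0, np.nan], [0.0, 1.0]])
    with pytest.raises(ValueError):
        survclust.hierarchical_cluster(m)


def test_cut_groups_boundaries(rng):
    m = _mat(rng.normal(size=(5, 6)))
    dendro = survclust.hierarchical_cluster(m)
    assert survclust.cut_groups(dendro, 1).nunique() == 1
    assert survclust.cut_groups(dendro, 6).nunique() == 6
    with pytest.raises(ValueError):
        survclust.cut_groups(dendro, 0)


def test_cut_groups_minority_is_group1(rng):
    n1, n2 = 14, 54
    X = rng.normal(size=(40, n1 + n2))
    X[:, :n1] += 8.0
    dendro = survclust.hierarchical_cluster(_mat(X))
    groups = survclust.cut_groups(dendro, 2)
    assert (groups.iloc[:n1] == 1).all()
    assert (groups.iloc[n1:] == 2).all()


# ---------------------------------------------------------- Kaplan–Meier

def test_km_hand_computed_product_limit():
    km = survclust.km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
    np.testing.assert_allclose(km.survival, [0.75, 0.50, 0.25, 0.0])
    assert km.median == 2


def test_km_all_censored_degenerate():
    km = survclust.km_estimate([5, 6, 7], [0, 0, 0])
    assert km.median is None
    assert km.survival.size == 0
    assert km.survival_at(100.0) == 1.0


def test_km_no_censoring_equals_empirical(rng):
    t = rng.exponential(10, size=40)
    km = survclust.km_estimate(t, np.ones_like(t))
    for u in km.times:
        assert km.survival_at(u) == pytest.approx((t > u).mean())


def test_km_agrees_with_lifelines(rng):
    from lifelines import KaplanMeierFitter

    t = rng.exponential(20, size=60)
    e = rng.integers(0, 2, size=60)
    e[0] = 1
    km = survclust.km_estimate(t, e)
    kmf = KaplanMeierFitter().fit(t, e)
    for u in km.times:
        assert km.survival_at(u) == pytest.approx(
            float(kmf.survival_function_at_times(u).iloc[0])
        )


def test_km_recovers_exponential_median(rng):
    t = rng.exponential(28 / np.log(2), size=500)
    km = survclust.km_estimate(t, np.ones_like(t))
    assert km.median == pytest.approx(28.0, rel=0.15)


# -------------------------------------------------------------- log-rank

def _breslow_score_chi2(t, e, x):
    """Cox score test at beta=0 with Breslow ties == log-rank chi2."""
    U = V = 0.0
    for u in np.unique(t[e == 1]):
        at_risk = t >= u
        d = int(((t == u) & (e == 1)).sum())
        n = int(at_risk.sum())
        x_r = x[at_risk]
        s_d = x[(t == u) & (e == 1)].sum()
        U += s_d - d * x_r.mean()
        if n > 1:
            V += d * (n - d) / (n - 1) * x_r.var()
    return U**2 / V


def test_logrank_matches_cox_score_test(rng):
    t = np.round(rng.exponential(10, size=80), 1)  # rounding induces ties
    e = (rng.random(80) < 0.7).astype(int)
    x = (rng.random(80) < 0.5).astype(float)
    e[x == 1] |= 0  # keep both groups with events
    stat, _ = survclust.logrank_test(t, e, x)
    assert stat == pytest.approx(_breslow_score_chi2(t, e, x), rel=1e-6)


def test_logrank_symmetric_patterns_give_zero():
    t = [1, 1, 2, 2, 3, 3]
    e = [1, 1, 1, 1, 0, 0]
    g = [0, 1, 0, 1, 0, 1]
    stat, p = survclust.logrank_test(t, e, g)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_label_swap_invariance(rng):
    t = rng.exponential(5, size=40)
    e = np.ones(40, dtype=int)
    g = rng.integers(0, 2, size=40)
    s1, p1 = survclust.logrank_test(t, e, g)
    s2, p2 = survclust.logrank_test(t, e, 1 - g)
    assert s1 == pytest.approx(s2)
    assert p1 == pytest.approx(p2)


def test_logrank_power_under_strong_separation(rng):
    hits = 0
    reps = 40
    for _ in range(reps):
        t0 = rng.exponential(50, size=50)
        t1 = rng.exponential(10, size=50)  # hazard ratio 5
        t = np.concatenate([t0, t1])
        g = np.repeat([0, 1], 50)
        _, p = survclust.logrank_test(t, np.ones(100, dtype=int), g)
        hits += p < 0.001
    assert hits / reps >= 0.95


def test_logrank_requires_two_groups():
    with pytest.raises(ValueError):
        survclust.logrank_test([1, 2], [1, 1], [0, 0])


# ------------------------------------------------------------------ Cox

def test_cox_matches_partial_likelihood_maximizer(rng):
    n = 30
    x = (rng.random(n) < 0.5).astype(float)
    t = np.round(rng.exponential(10 / np.exp(0.8 * x)), 1)
    e = (rng.random(n) < 0.8).astype(int)
    if e.sum() == 0:
        e[0] = 1
    fit = survclust.cox_fit(pd.DataFrame({"x": x}), t, e)
    res = minimize_scalar(efron_neg_loglik, args=(x, t, e), bounds=(-5, 5),
                          method="bounded", options={"xatol": 1e-10})
    assert fit.summary.loc["x", "coef"] == pytest.approx(res.x, abs=1e-6)


def test_cox_agrees_with_lifelines(rng):
    from lifelines import CoxPHFitter

    n = 120
    X = pd.DataFrame({"a": rng.normal(size=n),
                      "b": (rng.random(n) < 0.4).astype(float)})
    t = np.round(rng.exponential(10 / np.exp(0.6 * X["a"] - 0.4 * X["b"])), 1)
    e = (rng.random(n) < 0.75).astype(int)
    fit = survclust.cox_fit(X, t, e)
    df = X.copy()
    df["t"], df["e"] = t, e
    ll = CoxPHFitter().fit(df, duration_col="t", event_col="e")
    np.testing.assert_allclose(fit.summary["coef"], ll.summary["coef"], atol=1e-4)
    np.testing.assert_allclose(fit.summary["se"], ll.summary["se(coef)"], atol=1e-4)


def test_cox_breslow_ties_option(rng):
    t = np.repeat([1.0, 2.0, 3.0], 5)
    e = np.ones(15, dtype=int)
    x = rng.normal(size=15)
    efron = survclust.cox_fit(pd.DataFrame({"x": x}), t, e, ties="efron")
    breslow = survclust.cox_fit(pd.DataFrame({"x": x}), t, e, ties="breslow")
    assert efron.summary.loc["x", "coef"] != pytest.approx(
        breslow.summary.loc["x", "coef"], abs=1e-8
    )
    with pytest.raises(ValueError):
        survclust.cox_fit(pd.DataFrame({"x": x}), t, e, ties="exact")


def test_cox_separation_flagged():
    # perfectly separating covariate: monotone likelihood, no finite MLE
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    e = np.array([1, 1, 1, 1, 1, 1])
    x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    fit = survclust.cox_fit(pd.DataFrame({"x": x}), t, e)
    assert not fit.converged
    assert fit.summary.empty


def test_cox_no_events_errors():
    with pytest.raises(ValueError):
        survclust.cox_fit(pd.DataFrame({"x": [1.0, 0.0]}), [1, 2], [0, 0])


def test_cox_constant_covariate_errors():
    with pytest.raises(ValueError):
        survclust.cox_fit(pd.DataFrame({"x": [1.0, 1.0, 1.0]}), [1, 2, 3], [1, 1, 1])


def test_cox_covariate_scale_equivariance(rng):
    n = 60
    x = rng.normal(size=n)
    t = rng.exponential(1 / np.exp(0.5 * x))
    e = np.ones(n, dtype=int)
    f1 = survclust.cox_fit(pd.DataFrame({"x": x}), t, e)
    f2 = survclust.cox_fit(pd.DataFrame({"x": x * 10}), t, e)
    assert f2.summary.loc["x", "coef"] == pytest.approx(
        f1.summary.loc["x", "coef"] / 10, rel=1e-5
    )
    # and invariance to time rescaling
    f3 = survclust.cox_fit(pd.DataFrame({"x": x}), t * 12.0, e)
    assert f3.summary.loc["x", "coef"] == pytest.approx(
        f1.summary.loc["x", "coef"], rel=1e-6
    )


# --------------------------------------------------------- marker screen

def test_marker_screen_null_calibration(rng):
    n = 80
    X = rng.normal(5, 1, size=(60, n))
    mat = _mat(X)
    clin = pd.DataFrame(
        {"os_months": rng.exponential(50, n), "event": np.ones(n, dtype=int)},
        index=mat.columns,
    )
    screen = survclust.marker_screen(list(mat.index), mat, clin)
    frac = (screen["pvalue"] < 0.05).mean()
    assert frac <= 0.15


def test_marker_screen_recovers_hazard_gene(rng):
    n = 120
    X = rng.normal(0, 1, size=(5, n))
    risk = X[0]
    t = rng.exponential(1 / np.exp(1.0 * risk))
    mat = _mat(X)
    clin = pd.DataFrame(
        {"os_months": t, "event": np.ones(n, dtype=int)}, index=mat.columns
    )
    screen = survclust.marker_screen(list(mat.index), mat, clin)
    assert screen.loc["g0", "hr"] > 1
    assert screen.loc["g0", "pvalue"] < 0.05
    assert set(screen.columns) == {"hr", "ci_lower", "ci_upper", "pvalue", "status"}


def test_marker_screen_zero_variance_flagged(rng):
    X = rng.normal(size=(2, 30))
    X[1] = 7.0
    mat = _mat(X)
    clin = pd.DataFrame(
        {"os_months": rng.exponential(10, 30), "event": np.ones(30, dtype=int)},
        index=mat.columns,
    )
    screen = survclust.marker_screen(["g0", "g1"], mat, clin)
    assert screen.loc["g1", "status"] == "zero_variance"
    assert np.isnan(screen.loc["g1", "hr"])


# ----------------------------------------------------- multivariate Cox

def _clinical_frame(rng, n, hr_age=1.5, hr_met=3.0, hr_grp=5.0):
    age = rng.normal(50, 14, n)
    met = (rng.random(n) < 0.4).astype(float)
    grp1 = (rng.random(n) < 0.2).astype(float)
    lam = 0.01 * hr_age ** ((age - 50) / 10) * hr_met**met * hr_grp**grp1
    t = rng.exponential(1 / lam)
    c = rng.uniform(0, 300, n)
    clin = pd.DataFrame(
        {
            "age": age,
            "metastasis": np.where(met == 1, "yes", "no"),
            "os_months": np.minimum(t, c),
            "event": (t <= c).astype(int),
        },
        index=[f"s{i}" for i in range(n)],
    )
    groups = pd.Series(np.where(grp1 == 1, 1, 2), index=clin.index)
    return clin, groups


def test_multivariate_recovers_joint_effects(rng):
    coefs = []
    for _ in range(4):
        clin, groups = _clinical_frame(rng, 1000)
        fit = survclust.multivariate_fit(clin, groups)
        coefs.append(fit.summary["coef"])
    mean = pd.concat(coefs, axis=1).mean(axis=1)
    for cov, hr_true in [("age_per_10y", 1.5), ("metastasis", 3.0), ("group1", 5.0)]:
        assert mean[cov] == pytest.approx(np.log(hr_true), abs=0.15)


def test_multivariate_age_scale_consistency(rng):
    clin, groups = _clinical_frame(rng, 300)
    fit = survclust.multivariate_fit(clin, groups)
    cov_years = pd.DataFrame(
        {
            "age_years": clin["age"].astype(float),
            "metastasis": (clin["metastasis"] == "yes").astype(float),
            "group1": (groups == 1).astype(float),
        }
    )
    fit_years = survclust.cox_fit(cov_years, clin["os_months"], clin["event"])
    assert fit_years.summary.loc["age_years", "coef"] * 10 == pytest.approx(
        fit.summary.loc["age_per_10y", "coef"], rel=1e-4
    )


def test_multivariate_drops_incomplete_rows(rng):
    clin, groups = _clinical_frame(rng, 100)
    clin.loc[clin.index[:7], "metastasis"] = np.nan
    fit = survclust.multivariate_fit(clin, groups)
    assert fit.n == 93
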