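"""Survival evaluation: KM, log-rank, time-dependent ROC, cutoff, group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from irlncpair import (
    DataError,
    RiskScores,
    assign_groups,
    clinical_association,
    external_score_association,
    four_group_analysis,
    independent_prognostic,
    km_estimate,
    logrank,
    multi_marker_roc,
    optimal_cutoff,
    time_roc,
)
from irlncpair.evaluation import significance_stars
from tests.conftest import make_clinical, random_survival


# --- Kaplan-Meier ---------------------------------------------------------


def test_km_no_censoring_closed_form():
    km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
    np.testing.assert_allclose(km.surv, [0.75, 0.5, 0.25, 0.0])
    np.testing.assert_array_equal(km.n_risk, [4, 3, 2, 1])


def test_km_all_censored_is_unity():
    km = km_estimate([1, 2, 3], [0, 0, 0])
    assert km.times.size == 0
    assert km.at(99.0) == 1.0


def test_km_matches_lifelines_on_mixed_data():
    """Six-subject mixed censoring table cross-checked against the
    independent lifelines product-limit implementation."""
    from lifelines import KaplanMeierFitter

    times = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
    events = [1, 0, 1, 1, 0, 1]
    km = km_estimate(times, events)
    # hand product-limit: d/n at t=1: 1/6, t=2: 1/5, t=3: 1/3, t=5: 1/1
    np.testing.assert_allclose(
        km.surv, [5 / 6, 5 / 6 * 4 / 5, 5 / 6 * 4 / 5 * 2 / 3, 0.0]
    )
    kmf = KaplanMeierFitter().fit(times, events)
    for t in [0.5, 1, 2, 3, 4, 5, 6]:
        assert km.at(t) == pytest.approx(
            float(kmf.predict(t)), abs=1e-12
        )


@pytest.mark.parametrize("seed", range(5))
def test_km_equals_empirical_survival_uncensored(seed):
    rng = np.random.default_rng(seed)
    t = rng.exponential(3, 50)
    km = km_estimate(t, np.ones(50, dtype=int))
    for q in np.quantile(t, [0.1, 0.5, 0.9]):
        assert km.at(q) == pytest.approx((t > q).mean(), abs=1e-12)


def test_km_empty_error():
    with pytest.raises(DataError):
        km_estimate([], [])


# --- log-rank -------------------------------------------------------------


def test_logrank_identical_groups_null():
    t = [1, 2, 3, 4, 5.0] * 2
    e = [1, 0, 1, 1, 0] * 2
    g = ["a"] * 5 + ["b"] * 5
    chi2, p = logrank(g, t, e)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_relabel_invariance():
    rng = np.random.default_rng(1)
    t, e = random_survival(rng, 60)
    g = np.where(rng.random(60) > 0.5, "x", "y")
    chi2a, pa = logrank(g, t, e)
    flipped = np.where(g == "x", "y", "x")
    chi2b, pb = logrank(flipped, t, e)
    assert chi2a == pytest.approx(chi2b, rel=1e-12)
    assert pa == pytest.approx(pb, rel=1e-12)


def test_logrank_detects_strong_effect():
    rng = np.random.default_rng(2)
    n = 400
    g = np.where(np.arange(n) % 2 == 0, "high", "low")
    t = rng.exponential(5, n) * np.exp(-1.5 * (g == "high"))
    c = rng.uniform(0, 20, n)
    times, events = np.minimum(t, c), (t <= c).astype(int)
    _, p = logrank(g, times, events)
    assert p < 0.001


def test_logrank_empty_group_error():
    with pytest.raises(DataError):
        logrank(["a", "a"], [1, 2], [1, 1])


# --- time-dependent ROC ---------------------------------------------------


def test_perfect_marker_auc_one():
    t = np.array([1, 2, 3, 4, 5, 6, 7, 8.0])
    clin = make_clinical(t, np.ones(8, dtype=int))
    marker = pd.Series(-t, index=clin.sample_ids)
    roc = time_roc(marker, clin, horizon=4.5)
    assert roc.auc == pytest.approx(1.0)


def brute_force_binary_roc(x, y):
    """Confusion-matrix ROC for binary outcome y over cutpoints of x."""
    cuts = np.unique(x)
    sens = np.array([np.mean(x[y == 1] > c) for c in cuts])
    spec = np.array([np.mean(x[y == 0] <= c) for c in cuts])
    return cuts, sens, spec


@pytest.mark.parametrize("seed", range(5))
def test_uncensored_limit_equals_confusion_matrix(seed):
    """Without censoring before t the KM-based estimator reduces exactly to
    the empirical binary classification ROC for the outcome {T <= t}."""
    rng = np.random.default_rng(seed)
    n = 60
    t = rng.exponential(4, n)
    x = 0.8 * (-t) + rng.normal(0, 1, n)
    horizon = float(np.median(t))
    clin = make_clinical(t, np.ones(n, dtype=int))
    marker = pd.Series(x, index=clin.sample_ids)
    roc = time_roc(marker, clin, horizon)
    y = (t <= horizon).astype(int)
    cuts, sens, spec = brute_force_binary_roc(x, y)
    np.testing.assert_array_equal(roc.cutpoints, cuts)
    np.testing.assert_allclose(roc.sens, sens, atol=1e-10)
    np.testing.assert_allclose(roc.spec, spec, atol=1e-10)


@pytest.mark.parametrize("seed", range(3))
def test_auc_monotone_transform_invariance(seed):
    rng = np.random.default_rng(seed)
    t, e = random_survival(rng, 100)
    x = rng.normal(size=100)
    clin = make_clinical(t, e)
    m1 = pd.Series(x, index=clin.sample_ids)
    m2 = pd.Series(np.exp(2 * x), index=clin.sample_ids)
    r1 = time_roc(m1, clin, horizon=3.0)
    r2 = time_roc(m2, clin, horizon=3.0)
    assert r1.auc == pytest.approx(r2.auc, abs=1e-12)


def test_no_events_by_horizon_error():
    clin = make_clinical([5, 6, 7.0], [1, 1, 1])
    marker = pd.Series([1, 2, 3.0], index=clin.sample_ids)
    with pytest.raises(DataError):
        time_roc(marker, clin, horizon=1.0)


# --- optimal cutoff -------------------------------------------------------


def exhaustive_cutoff(roc):
    best, best_y = None, -np.inf
    for c, s, sp in zip(roc.cutpoints, roc.sens, roc.spec):
        y = s + sp - 1
        if y > best_y:  # strict: first (smallest) cutpoint wins ties
            best, best_y = c, y
    return best


@pytest.mark.parametrize("seed", range(10))
def test_optimal_cutoff_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    n = 50
    t, e = random_survival(rng, n)
    x = -t + rng.normal(0, 1.5, n)
    clin = make_clinical(t, e)
    roc = time_roc(pd.Series(x, index=clin.sample_ids), clin, horizon=3.0)
    assert optimal_cutoff(roc) == exhaustive_cutoff(roc)


def test_separating_marker_cutoff_between_classes():
    t = np.array([1, 1.5, 2, 8, 9, 10.0])
    clin = make_clinical(t, np.ones(6, dtype=int))
    x = pd.Series([10, 9, 8, 1, 2, 3.0], index=clin.sample_ids)
    roc = time_roc(x, clin, horizon=5.0)
    cut = optimal_cutoff(roc)
    assert 3.0 <= cut < 8.0


def test_flat_roc_returns_smallest_cutpoint():
    t = np.array([1, 2, 3, 4.0])
    clin = make_clinical(t, np.ones(4, dtype=int))
    x = pd.Series([5.0, 5.0, 5.0, 5.0], index=clin.sample_ids)
    roc = time_roc(x, clin, horizon=2.5)
    assert optimal_cutoff(roc) == roc.cutpoints[0]


# --- multi-marker ROC -----------------------------------------------------


def test_multi_marker_duplicated_and_recoded():
    rng = np.random.default_rng(5)
    n = 120
    t, e = random_survival(rng, n)
    stage = rng.integers(1, 5, n).astype(float)
    clin = make_clinical(t, e, age=rng.normal(65, 8, n), stage=stage)
    score = RiskScores(pd.Series(rng.normal(size=n), index=clin.sample_ids))
    rocs = multi_marker_roc(score, clin, horizon=3.0, covariates=("age", "stage"))
    assert set(rocs) == {"risk", "age", "stage"}
    # strictly increasing re-coding of an ordinal leaves its AUC unchanged
    clin2 = make_clinical(t, e, age=clin.data["age"], stage=stage**2 + 7)
    rocs2 = multi_marker_roc(score, clin2, horizon=3.0, covariates=("age", "stage"))
    assert rocs["stage"].auc == pytest.approx(rocs2["stage"].auc, abs=1e-12)


def test_constant_covariate_flagged():
    rng = np.random.default_rng(6)
    n = 80
    t, e = random_survival(rng, n)
    clin = make_clinical(t, e, stage=np.full(n, 2.0))
    score = RiskScores(pd.Series(rng.normal(size=n), index=clin.sample_ids))
    rocs = multi_marker_roc(score, clin, horizon=3.0, covariates=("stage",))
    assert np.isnan(rocs["stage"].auc)


# --- association tests ----------------------------------------------------


def grouped_scores(values, index, cutoff=0.0):
    return assign_groups(RiskScores(pd.Series(values, index=index)), cutoff)


def test_chi_square_closed_form_2x2():
    """chi2 for a 2x2 table recomputed from the textbook formula
    n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    a, b, c, d = 50, 10, 10, 50
    n = a + b + c + d
    expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    chi2, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)[:2]
    assert chi2 == pytest.approx(expected, rel=1e-12)
    # and via clinical_association: trait level 1 <-> high group etc.
    trait = [1.0] * (a + b) + [2.0] * (c + d)
    grp_scores = np.concatenate([np.ones(a), -np.ones(b), np.ones(c), -np.ones(d)])
    idx = [f"s{i}" for i in range(n)]
    rng = np.random.default_rng(7)
    t, e = random_survival(rng, n)
    clin = make_clinical(t, e, index=idx, stage=trait)
    scores = grouped_scores(grp_scores, idx)
    res = clinical_association(scores, clin)
    assert res.loc["stage", "chi2"] == pytest.approx(expected, rel=1e-12)


def test_identical_scores_rank_test_unity():
    rng = np.random.default_rng(8)
    n = 60
    t, e = random_survival(rng, n)
    idx = [f"s{i}" for i in range(n)]
    clin = make_clinical(t, e, index=idx, stage=rng.integers(1, 4, n).astype(float))
    scores = RiskScores(pd.Series(np.zeros(n), index=idx))
    scores = assign_groups(scores, cutoff=-1.0)  # all high
    # one-level group: chi-square not defined; use a mixed-group variant
    scores = RiskScores(pd.Series(np.zeros(n), index=idx))
    grp = pd.Series(["high" if i % 2 else "low" for i in range(n)], index=idx)
    scores = RiskScores(scores.scores, grp, 0.0, "roc_optimal")
    res = clinical_association(scores, clin)
    assert res.loc["stage", "rank_p"] == 1.0


def test_external_association_nulls_and_stars():
    rng = np.random.default_rng(9)
    n = 200
    idx = [f"s{i}" for i in range(n)]
    scores = grouped_scores(np.where(np.arange(n) < n // 2, 1.0, -1.0), idx)
    same = rng.normal(size=n // 2)
    feats = pd.DataFrame(
        {
            "identical": np.concatenate([same, same]),
            "shifted": rng.normal(0, 1, n) + (np.arange(n) < n // 2) * 1.0,
        },
        index=idx,
    )
    res = external_score_association(scores, feats)
    assert res.loc["identical", "p_value"] == pytest.approx(1.0)
    assert res.loc["identical", "stars"] == ""
    assert res.loc["shifted", "p_value"] < 0.001
    assert res.loc["shifted", "stars"] == "***"


@pytest.mark.parametrize(
    "p,stars", [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.2, "")]
)
def test_star_thresholds(p, stars):
    assert significance_stars(p) == stars


# --- independent prognostic ----------------------------------------------


def test_independent_prognostic_structure():
    rng = np.random.default_rng(10)
    n = 300
    idx = [f"s{i}" for i in range(n)]
    score = rng.normal(size=n)
    t = rng.exponential(5, n) * np.exp(-0.9 * score)
    c = rng.uniform(0, 15, n)
    clin = make_clinical(
        np.minimum(t, c), (t <= c).astype(int), index=idx,
        age=rng.normal(65, 9, n), stage=rng.integers(1, 5, n).astype(float),
    )
    scores = RiskScores(pd.Series(score, index=idx))
    uni, multi = independent_prognostic(scores, clin)
    for df in (uni, multi):
        assert {"risk_score", "age", "stage"} <= set(df.index)
        np.testing.assert_allclose(
            df["HR"], np.exp(df["coef"]), rtol=1e-9
        )
    # the driving score is significant in both tables; noise covariates not
    assert uni.loc["risk_score", "p_value"] < 1e-6
    assert multi.loc["risk_score", "p_value"] < 1e-6
    assert uni.loc["age", "p_value"] > 0.001


def test_multivariate_single_covariate_reduces_to_univariate():
    rng = np.random.default_rng(11)
    n = 100
    idx = [f"s{i}" for i in range(n)]
    t, e = random_survival(rng, n)
    clin = make_clinical(t, e, index=idx)
    scores = RiskScores(pd.Series(rng.normal(size=n), index=idx))
    uni, multi = independent_prognostic(scores, clin)
    assert multi.loc["risk_score", "coef"] == pytest.approx(
        uni.loc["risk_score", "coef"], abs=1e-10
    )


# --- four-group analysis --------------------------------------------------


def test_four_group_concordant_models_two_subgroups():
    rng = np.random.default_rng(12)
    n = 80
    idx = [f"s{i}" for i in range(n)]
    t, e = random_survival(rng, n)
    clin = make_clinical(t, e, index=idx)
    vals = rng.normal(size=n)
    s1 = grouped_scores(vals, idx)
    s2 = grouped_scores(vals, idx)
    res = four_group_analysis(s1, s2, clin)
    assert sorted(res.curves) == sorted(["high+high", "low+low"])
    assert set(res.empty_subgroups) == {"high+low", "low+high"}


def test_four_group_partition_and_ordering():
    rng = np.random.default_rng(13)
    n = 400
    idx = [f"s{i}" for i in range(n)]
    u = rng.normal(size=n)
    v = rng.normal(size=n)
    t = rng.exponential(6, n) * np.exp(-0.8 * (u > 0) - 0.8 * (v > 0))
    c = rng.uniform(0, 20, n)
    clin = make_clinical(np.minimum(t, c), (t <= c).astype(int), index=idx)
    res = four_group_analysis(grouped_scores(u, idx), grouped_scores(v, idx), clin)
    sizes = {g: int((res.labels == g).sum()) for g in res.curves}
    assert sum(sizes.values()) == n
    # doubly-high-risk subgroup has the worst survival at a mid horizon
    at3 = {g: res.curves[g].at(3.0) for g in res.curves}
    assert at3["high+high"] == min(at3.values())
    assert res.global_test[1] < 0.001
    assert len(res.pairwise) == 6
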