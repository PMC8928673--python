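"""Survival evaluation: KM curves, log-rank, time-dependent ROC, cutoffs,
clinical association, independent prognostic Cox, and the combined
four-group analysis.

The time-dependent ROC at horizon t uses the Kaplan–Meier-based
cumulative-case estimator: for marker X and cutpoint c,

    sens(c, t) = [1 - S(t | X > c)] P(X > c) / [1 - S(t)]
    spec(c, t) = S(t | X <= c) P(X <= c) / S(t)

with every survival probability a product-limit estimate inside the
marker-defined subset; AUC is the trapezoid over (1 - spec, sens). This
handles right-censoring before the horizon, and in the uncensored limit
reduces exactly to the empirical confusion-matrix ROC for the binary
outcome {T <= t}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats

from .io import ClinicalTable, DataError
from .modeling import RiskScores
from .screening import CoxFit, cox_fits_frame, fit_cox, fit_cox_single

logger = logging.getLogger("irlncpair")


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit survival curve: S(t) evaluated at the event times."""

    times: np.ndarray
    surv: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    label: str = ""

    def at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous; S = 1 before the
        first event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.surv[idx])


def km_estimate(times, events, label: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod_{t_i<=t} (1 - d_i/n_i).

    ``times``/``events`` are per-subject follow-up and 0/1 event flags.
    Only distinct observed-event times appear in the curve.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise DataError("empty survival data")
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    uniq, start = np.unique(t, return_index=True)
    n = t.size
    at_risk = n - start  # subjects with follow-up >= each distinct time
    d = np.add.reduceat(e, start)  # events at each distinct time
    has_event = d > 0
    ev_times = uniq[has_event]
    n_risk = at_risk[has_event]
    n_event = d[has_event]
    surv = np.cumprod(1.0 - n_event / n_risk)
    return KMCurve(ev_times, surv, n_risk, n_event, label)


def km_at(times, events, horizon: float) -> float:
    """S(horizon) by the product-limit estimator (fast scalar path)."""
    return km_estimate(times, events).at(horizon)


def logrank(groups, times, events) -> tuple[float, float]:
    """Log-rank test across groups; two groups give the classic chi2(1) test."""
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise DataError("log-rank requires at least two groups")
    for lab in labels:
        if (groups == lab).sum() == 0:
            raise DataError(f"empty group {lab!r}")
    if len(labels) == 2:
        m = groups == labels[0]
        res = logrank_test(times[m], times[~m], events[m], events[~m])
    else:
        res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# time-dependent ROC
# ---------------------------------------------------------------------------


@dataclass
class TimeROC:
    """ROC at a fixed horizon for a survival marker."""

    horizon: float
    cutpoints: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    marker: str = ""


def _as_marker(scores) -> pd.Series:
    if isinstance(scores, RiskScores):
        return scores.scores
    return pd.Series(scores)


def time_roc(scores, clin: ClinicalTable, horizon: float, marker: str = "risk") -> TimeROC:
    """Time-dependent ROC of a marker at one horizon (KM-based estimator)."""
    x = _as_marker(scores)
    shared = [s for s in x.index if s in clin.sample_ids]
    if not shared:
        raise DataError("no overlap between marker and clinical samples")
    x = x.loc[shared].to_numpy(float)
    sub = clin.data.loc[shared]
    times = sub["os_time"].to_numpy(float)
    events = sub["os_event"].to_numpy(int)
    if not ((times <= horizon) & (events == 1)).any():
        raise DataError(f"no events observed by horizon {horizon}")
    s_t = km_at(times, events, horizon)
    if s_t >= 1.0:
        raise DataError(f"no KM-estimated risk by horizon {horizon}")

    cutpoints = np.unique(x)
    sens = np.empty(cutpoints.size)
    spec = np.empty(cutpoints.size)
    for i, c in enumerate(cutpoints):
        m = x > c
        p_high = m.mean()
        s_high = km_at(times[m], events[m], horizon) if m.any() else 1.0
        s_low = km_at(times[~m], events[~m], horizon) if (~m).any() else 1.0
        sens[i] = (1.0 - s_high) * p_high / (1.0 - s_t)
        spec[i] = s_low * (1.0 - p_high) / s_t if s_t > 0 else np.nan
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)

    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # ties in FPR ordered by sensitivity
    xs = np.concatenate([[0.0], fpr[order], [1.0]])
    ys = np.concatenate([[0.0], sens[order], [1.0]])
    auc = float(np.trapezoid(ys, xs))
    return TimeROC(horizon, cutpoints, sens, spec, auc, marker)


def optimal_cutoff(roc: TimeROC) -> float:
    """Cutpoint maximizing the Youden index sens + spec - 1.

    Ties break toward the smaller cutoff.
    """
    youden = roc.sens + roc.spec - 1.0
    return float(roc.cutpoints[int(np.argmax(youden))])


def multi_marker_roc(
    scores, clin: ClinicalTable, horizon: float, covariates=("age", "stage", "t_stage", "n_stage", "m_stage")
) -> dict:
    """One TimeROC per marker (risk score + clinical ordinals), complete cases.

    Constant covariates are flagged with an all-NaN ROC (AUC undefined).
    """
    x = _as_marker(scores)
    shared = [s for s in x.index if s in clin.sample_ids]
    sub = clin.data.loc[shared]
    cols = [c for c in covariates if c in sub.columns]
    complete = sub[cols].notna().all(axis=1)
    keep = sub.index[complete]
    cc = ClinicalTable(sub.loc[keep], clin.time_unit)
    out = {"risk": time_roc(x.loc[keep], cc, horizon, marker="risk")}
    for c in cols:
        vals = sub.loc[keep, c]
        if vals.nunique() < 2:
            logger.warning("covariate %r is constant; AUC undefined", c)
            out[c] = TimeROC(horizon, np.array([]), np.array([]), np.array([]), np.nan, c)
            continue
        out[c] = time_roc(vals, cc, horizon, marker=c)
    return out


# ---------------------------------------------------------------------------
# group association tests
# ---------------------------------------------------------------------------


def significance_stars(p: float) -> str:
    """Conventional star labels: *** p<0.001, ** p<0.01, * p<0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def clinical_association(scores: RiskScores, clin: ClinicalTable) -> pd.DataFrame:
    """Associate risk groups and scores with each clinical trait.

    Per trait: a chi-square test of the trait x risk-group contingency
    table, plus a rank test of the score across trait levels (rank-sum for
    two levels, Kruskal-Wallis for more).
    """
    if scores.group is None:
        raise DataError("scores must be grouped before clinical association")
    shared = [s for s in scores.sample_ids if s in clin.sample_ids]
    sub = clin.data.loc[shared]
    grp = scores.group.loc[shared]
    val = scores.scores.loc[shared]
    rows = []
    for trait in [c for c in ClinicalTable.COVARIATES if c in sub.columns]:
        tv = sub[trait]
        ok = tv.notna()
        levels = sorted(tv[ok].unique())
        if len(levels) < 2:
            logger.info("trait %r has one level; skipped", trait)
            continue
        table = pd.crosstab(tv[ok], grp[ok])
        chi2, chi_p = stats.chi2_contingency(table.to_numpy(), correction=False)[:2]
        by_level = [val[ok][tv[ok] == l].to_numpy() for l in levels]
        flat = np.concatenate(by_level)
        if np.all(flat == flat[0]):  # degenerate: identical scores everywhere
            rank_stat, rank_p = 0.0, 1.0
            rank_test = "ranksum" if len(levels) == 2 else "kruskal"
        elif len(levels) == 2:
            rank_stat, rank_p = stats.ranksums(by_level[0], by_level[1])
            rank_test = "ranksum"
        else:
            rank_stat, rank_p = stats.kruskal(*by_level)
            rank_test = "kruskal"
        rows.append(
            {
                "trait": trait,
                "chi2": float(chi2),
                "chi2_p": float(chi_p),
                "rank_test": rank_test,
                "rank_stat": float(rank_stat),
                "rank_p": float(rank_p),
                "stars": significance_stars(float(chi_p)),
            }
        )
    return pd.DataFrame(rows).set_index("trait") if rows else pd.DataFrame()


def independent_prognostic(
    scores: RiskScores, clin: ClinicalTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariate Cox per covariate plus one joint multivariate Cox.

    Covariates: the risk score and every available clinical ordinal.
    Returns (univariate table, multivariate table) in coef/HR/CI/p layout.
    """
    shared = [s for s in scores.sample_ids if s in clin.sample_ids]
    sub = clin.data.loc[shared]
    covs = pd.DataFrame({"risk_score": scores.scores.loc[shared]})
    for c in ClinicalTable.COVARIATES:
        if c in sub.columns and sub[c].notna().sum() > 0 and sub[c].nunique() > 1:
            covs[c] = sub[c]
    uni: list[CoxFit] = []
    for c in covs.columns:
        ok = covs[c].notna()
        fit = fit_cox_single(
            covs.loc[ok, c].to_numpy(float),
            sub.loc[ok, "os_time"].to_numpy(),
            sub.loc[ok, "os_event"].to_numpy(),
            name=c,
        )
        uni.append(fit)
    complete = covs.notna().all(axis=1)
    df = covs[complete].astype(float)
    df["os_time"] = sub.loc[complete, "os_time"]
    df["os_event"] = sub.loc[complete, "os_event"]
    multi = fit_cox(df)
    return cox_fits_frame(uni), cox_fits_frame(multi)


def external_score_association(
    groups: RiskScores, feature_table: pd.DataFrame
) -> pd.DataFrame:
    """Rank-sum tests of per-sample external features between risk groups.

    ``feature_table`` is samples x features (e.g. immune-infiltration
    fractions, checkpoint-gene expression, drug IC50). Features with no
    usable overlap are skipped.
    """
    if groups.group is None:
        raise DataError("scores must be grouped first")
    shared = [s for s in feature_table.index if s in groups.sample_ids]
    if not shared:
        raise DataError("no overlap between feature table and grouped samples")
    grp = groups.group.loc[shared]
    rows = []
    for feat in feature_table.columns:
        vals = feature_table.loc[shared, feat]
        ok = vals.notna()
        hi = vals[ok & (grp == "high")].to_numpy(float)
        lo = vals[ok & (grp == "low")].to_numpy(float)
        if hi.size == 0 or lo.size == 0:
            logger.info("feature %r has no usable overlap; skipped", feat)
            continue
        stat, p = stats.ranksums(hi, lo)
        rows.append(
            {
                "feature": feat,
                "statistic": float(stat),
                "p_value": float(p),
                "median_high": float(np.median(hi)),
                "median_low": float(np.median(lo)),
                "stars": significance_stars(float(p)),
            }
        )
    return pd.DataFrame(rows).set_index("feature") if rows else pd.DataFrame()


# ---------------------------------------------------------------------------
# combined four-group analysis
# ---------------------------------------------------------------------------


@dataclass
class FourGroupResult:
    labels: pd.Series  # per-sample subgroup label "pair+exp" e.g. "high+low"
    curves: dict  # subgroup -> KMCurve (non-empty subgroups)
    global_test: tuple  # (chi2, p) over non-empty subgroups
    pairwise: pd.DataFrame  # pairwise log-rank chi2/p
    empty_subgroups: list


def four_group_analysis(
    pair_scores: RiskScores, exp_scores: RiskScores, clin: ClinicalTable
) -> FourGroupResult:
    """Cross-classify samples by pair-risk and expression-risk group.

    Subgroups {high+high, high+low, low+high, low+low} are compared by KM
    curves, a global log-rank over the non-empty subgroups, and pairwise
    log-rank tests. Empty subgroups are retained in the report but
    excluded from testing.
    """
    for sc in (pair_scores, exp_scores):
        if sc.group is None:
            raise DataError("both score sets must be grouped")
    shared = [
        s
        for s in pair_scores.sample_ids
        if s in exp_scores.sample_ids and s in clin.sample_ids
    ]
    if not shared:
        raise DataError("no common samples across the two models and clinical data")
    labels = pd.Series(
        [f"{pair_scores.group[s]}+{exp_scores.group[s]}" for s in shared],
        index=pd.Index(shared),
    )
    sub = clin.data.loc[shared]
    all_subgroups = ["high+high", "high+low", "low+high", "low+low"]
    curves = {}
    empty = []
    for g in all_subgroups:
        m = labels == g
        if m.sum() == 0:
            empty.append(g)
            logger.info("subgroup %r is empty; excluded from tests", g)
            continue
        curves[g] = km_estimate(
            sub.loc[m.to_numpy(), "os_time"], sub.loc[m.to_numpy(), "os_event"], label=g
        )
    nonempty = [g for g in all_subgroups if g not in empty]
    if len(nonempty) >= 2:
        keep = labels.isin(nonempty)
        global_test = logrank(
            labels[keep].to_numpy(),
            sub.loc[keep.to_numpy(), "os_time"],
            sub.loc[keep.to_numpy(), "os_event"],
        )
    else:
        global_test = (np.nan, np.nan)
    rows = []
    for i, g1 in enumerate(nonempty):
        for g2 in nonempty[i + 1 :]:
            m = labels.isin([g1, g2])
            chi2, p = logrank(
                labels[m].to_numpy(),
                sub.loc[m.to_numpy(), "os_time"],
                sub.loc[m.to_numpy(), "os_event"],
            )
            rows.append({"group_a": g1, "group_b": g2, "chi2": chi2, "p_value": p})
    pairwise = pd.DataFrame(rows)
    return FourGroupResult(labels, curves, global_test, pairwise, empty)
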