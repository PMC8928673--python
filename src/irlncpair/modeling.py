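"""Signature selection and risk models.

Pipeline: univariate Cox on valid pair indicators -> repeated k-fold
cross-validated L1-penalized (lasso) Cox with selection-frequency
aggregation -> one joint multivariate Cox fit whose coefficients define

    RiskScore(sample) = sum_i beta_i * S_i(sample)

where S_i is the 0/1 pair indicator (pair-risk model) or the lncRNA's
log2(x+1) expression (expression-risk model).

The repeated lasso runs a fresh fold split per repeat, picks the penalty
minimizing mean cross-validated partial-likelihood deviance, refits the
whole data at that penalty, and records the nonzero-coefficient feature
set; final selection keeps features whose selection frequency across
repeats exceeds a threshold (default 0.5). The whole procedure is
seed-reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.exceptions import ConvergenceError
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .io import ClinicalTable, DataError
from .pairing import PairMatrix, pair_id, parse_pair_id
from .screening import CoxFit, fit_cox, fit_cox_single, log2p1

logger = logging.getLogger("irlncpair")


@dataclass
class RiskModel:
    """A fitted signature: named features with multivariate Cox coefficients."""

    kind: str  # "pair" or "expression"
    features: list
    coefficients: np.ndarray
    fit_stats: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.features) != len(self.coefficients):
            raise DataError("features and coefficients must have equal length")
        if self.kind not in ("pair", "expression"):
            raise DataError(f"unknown model kind {self.kind!r}")

    def signature_genes(self) -> list:
        """Distinct lncRNAs appearing in the signature (pair models: union)."""
        if self.kind == "expression":
            return list(self.features)
        genes: list = []
        for f in self.features:
            for g in parse_pair_id(f):
                if g not in genes:
                    genes.append(g)
        return genes

    def to_json(self, path) -> None:
        from .screening import cox_fits_frame

        payload = {
            "kind": self.kind,
            "features": list(self.features),
            "coefficients": [float(c) for c in self.coefficients],
            "fit_stats": cox_fits_frame(self.fit_stats).reset_index().to_dict("records")
            if self.fit_stats
            else [],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(payload["kind"], payload["features"], payload["coefficients"])


@dataclass
class RiskScores:
    """Per-sample risk scores, optionally split at a cutoff into groups."""

    scores: pd.Series
    group: pd.Series | None = None
    cutoff: float | None = None
    cutoff_rule: str | None = None  # "roc_optimal" or "median"

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.index

    def high_samples(self) -> pd.Index:
        return self.scores.index[self.group.to_numpy() == "high"]

    def low_samples(self) -> pd.Index:
        return self.scores.index[self.group.to_numpy() == "low"]


def assign_groups(
    scores: RiskScores, cutoff: float | None = None, rule: str = "roc_optimal"
) -> RiskScores:
    """Split samples into high/low at a cutoff (group = high iff score > cutoff).

    With ``rule="median"`` the cutoff is the median score and ``cutoff``
    is ignored.
    """
    if rule == "median":
        cutoff = float(scores.scores.median())
    elif cutoff is None:
        raise DataError("an explicit cutoff is required unless rule='median'")
    group = pd.Series(
        np.where(scores.scores.to_numpy() > cutoff, "high", "low"),
        index=scores.scores.index,
    )
    return RiskScores(scores.scores, group, float(cutoff), rule)


# ---------------------------------------------------------------------------
# univariate pair screen
# ---------------------------------------------------------------------------


def unicox_pairs(
    pm: PairMatrix, clin: ClinicalTable, p_max: float = 0.05
) -> list[CoxFit]:
    """Univariate Cox fit per valid pair on its binary indicator.

    Pairs whose fit fails (complete separation, non-convergence) are
    flagged with NaN statistics and excluded from passing.
    """
    ind = pm.valid_indicators()
    if ind.shape[0] == 0:
        raise DataError("no valid pairs to screen")
    shared = [s for s in ind.columns if s in clin.sample_ids]
    sub = clin.data.loc[shared]
    if int(sub["os_event"].sum()) < 10:
        raise DataError("pair Cox screen needs >= 10 observed events")
    time = sub["os_time"].to_numpy()
    event = sub["os_event"].to_numpy()
    fits = []
    n_failed = 0
    for pid, row in ind[shared].iterrows():
        try:
            fit = fit_cox_single(row.to_numpy(float), time, event, name=pid)
        except (ConvergenceError, ValueError):
            n_failed += 1
            fits.append(CoxFit(pid, np.nan, np.nan, np.nan, np.nan, np.nan,
                               int(event.sum()), passed=False))
            continue
        fit.passed = fit.p_value < p_max
        fits.append(fit)
    if n_failed:
        logger.warning("pair Cox screen: %d pair(s) failed to converge", n_failed)
    logger.info(
        "pair Cox screen: %d/%d pairs passed (p < %g)",
        sum(f.passed for f in fits), len(fits), p_max,
    )
    return fits


# ---------------------------------------------------------------------------
# repeated cross-validated lasso Cox
# ---------------------------------------------------------------------------


def cox_partial_loglik(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray
) -> float:
    """Breslow partial log-likelihood of ``beta`` on (X, time, event)."""
    order = np.argsort(-time, kind="stable")  # decreasing time
    X = X[order]
    time = time[order]
    event = event[order]
    eta = X @ beta
    # guard overflow; constant shifts cancel in the partial likelihood
    eta = eta - eta.max()
    cum = np.logaddexp.accumulate(eta)  # log sum exp over risk set (t >= t_i)
    # samples tied on time share the same risk set: take the last index of
    # each tie block (largest cumulated sum at that time)
    _, inv, counts = np.unique(-time, return_inverse=True, return_counts=True)
    block_end = np.cumsum(counts) - 1
    log_risk = cum[block_end[inv]]
    return float(np.sum(event * (eta - log_risk)))


@dataclass
class LassoSelection:
    """Outcome of the repeated cross-validated lasso."""

    selected: list
    frequencies: pd.Series
    n_repeats: int
    freq_threshold: float


def _cv_lasso_once(
    X: np.ndarray,
    y,
    time: np.ndarray,
    event: np.ndarray,
    k_folds: int,
    rs: int,
    alphas: np.ndarray,
) -> np.ndarray:
    """One CV round: per-alpha mean test-fold deviance -> nonzero mask at best alpha."""
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=rs)
    dev = np.zeros(len(alphas))
    counts = np.zeros(len(alphas))
    for train, test in kf.split(X):
        if event[test].sum() == 0 or event[train].sum() == 0:
            continue
        est = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=alphas, fit_baseline_model=False, normalize=False
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                est.fit(X[train], y[train])
            except (ValueError, ArithmeticError):
                continue
        coefs = est.coef_  # n_features x n_fitted_alphas
        fitted = np.asarray(est.alphas_)
        for j, a in enumerate(alphas):
            jj = int(np.argmin(np.abs(fitted - a)))
            ll = cox_partial_loglik(X[test], time[test], event[test], coefs[:, jj])
            dev[j] += -2.0 * ll
            counts[j] += 1
    if counts.max() == 0:
        raise DataError("cross-validation produced no usable folds")
    mean_dev = np.where(counts > 0, dev / np.maximum(counts, 1), np.inf)
    best = alphas[int(np.argmin(mean_dev))]
    est = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=[best], fit_baseline_model=False, normalize=False
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return np.abs(est.coef_[:, 0]) > 0


def lasso_select(
    candidates: pd.DataFrame,
    clin: ClinicalTable,
    n_repeats: int = 1000,
    k_folds: int = 10,
    freq_threshold: float = 0.5,
    seed: int = 0,
    n_alphas: int = 100,
) -> LassoSelection:
    """Repeated cross-validated lasso Cox with frequency aggregation.

    Parameters
    ----------
    candidates
        Feature rows x sample columns (binary pair indicators or
        expression covariates).
    clin
        Survival outcomes; samples are joined on IDs.
    n_repeats
        Number of independent CV rounds, each with a fresh fold split.
    freq_threshold
        A feature is selected iff its nonzero frequency across repeats
        exceeds this value.
    """
    if candidates.shape[0] < 2:
        raise DataError("lasso selection needs >= 2 candidate features")
    shared = [s for s in candidates.columns if s in clin.sample_ids]
    sub = clin.data.loc[shared]
    X = candidates[shared].to_numpy(float).T
    time = sub["os_time"].to_numpy(float)
    event = sub["os_event"].to_numpy(int)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    # one shared data-driven penalty grid (glmnet-style log-spaced path)
    probe = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.01,
        fit_baseline_model=False, normalize=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        probe.fit(X, y)
    alphas = np.asarray(probe.alphas_)

    ss = np.random.SeedSequence([seed, 3])
    fold_seeds = ss.generate_state(n_repeats) % (2**31 - 1)
    hits = np.zeros(candidates.shape[0])
    for rep in range(n_repeats):
        mask = _cv_lasso_once(X, y, time, event, k_folds, int(fold_seeds[rep]), alphas)
        hits += mask
    freq = pd.Series(hits / n_repeats, index=candidates.index)
    selected = list(freq.index[freq > freq_threshold])
    if not selected:
        raise DataError(
            "no feature exceeded the selection-frequency threshold; "
            "revise the threshold or penalty grid"
        )
    logger.info(
        "lasso selection: %d/%d features kept (freq > %g over %d repeats)",
        len(selected), candidates.shape[0], freq_threshold, n_repeats,
    )
    return LassoSelection(selected, freq, n_repeats, freq_threshold)


# ---------------------------------------------------------------------------
# multivariate fit and risk scores
# ---------------------------------------------------------------------------


def _drop_collinear(df: pd.DataFrame) -> pd.DataFrame:
    """Keep a maximal left-to-right linearly independent column subset."""
    keep: list = []
    arr = df.to_numpy(float)
    cur_rank = 0
    for j, col in enumerate(df.columns):
        cand = arr[:, [df.columns.get_loc(c) for c in keep] + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > cur_rank:
            keep.append(col)
            cur_rank = r
        else:
            logger.warning("dropping collinear feature %r from multivariate fit", col)
    return df[keep]


def fit_multicox(
    features: pd.DataFrame, clin: ClinicalTable, kind: str = "pair"
) -> RiskModel:
    """One joint Cox PH fit over the selected features.

    ``features`` has feature rows x sample columns. Perfectly collinear
    columns (e.g. duplicated pairs) are dropped with a warning before
    fitting.
    """
    shared = [s for s in features.columns if s in clin.sample_ids]
    sub = clin.data.loc[shared]
    design = features[shared].T.astype(float)
    if int(sub["os_event"].sum()) <= design.shape[1]:
        raise DataError("need more observed events than features for a joint fit")
    design = _drop_collinear(design)
    df = design.copy()
    df["os_time"] = sub["os_time"].to_numpy()
    df["os_event"] = sub["os_event"].to_numpy()
    fits = fit_cox(df)
    coefs = np.array([f.coef for f in fits])
    return RiskModel(kind, [f.feature_id for f in fits], coefs, fits)


def risk_score(model: RiskModel, features: pd.DataFrame) -> RiskScores:
    """RiskScore = sum_i beta_i * S_i over the model's features.

    ``features`` (rows = features, columns = samples) must cover every
    model feature; extra rows are ignored.
    """
    missing = [f for f in model.features if f not in features.index]
    if missing:
        raise DataError(f"feature(s) missing from matrix: {missing}")
    S = features.loc[model.features].to_numpy(float)
    scores = pd.Series(model.coefficients @ S, index=features.columns)
    return RiskScores(scores)


def fit_expression_model(
    core_lnc_values: pd.DataFrame, clin: ClinicalTable
) -> tuple[RiskModel, RiskScores]:
    """Expression-risk model on the signature genes' log2(x+1) expression.

    Fits the joint Cox model and assigns high/low groups at the median
    risk value.
    """
    log_expr = pd.DataFrame(
        log2p1(core_lnc_values.to_numpy()),
        index=core_lnc_values.index,
        columns=core_lnc_values.columns,
    )
    model = fit_multicox(log_expr, clin, kind="expression")
    scores = risk_score(model, log_expr)
    scores = assign_groups(scores, rule="median")
    return model, scores
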