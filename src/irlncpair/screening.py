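"""The three-filter cascade selecting core immune-related lncRNAs.

Order of operations: (1) immune co-expression (Pearson r > 0.5, p < 0.001
against at least one immune gene), (2) tumor-vs-normal differential
expression (|log2 fold change| > 2, rank-sum p < 0.05), (3) univariate Cox
survival screen (p < 0.05), then the intersection of (2) and (3) yields the
core set used to build pairs.

Correlation and Cox fits operate on log2(x + 1) expression; the
differential screen's fold change is the difference of mean log2(x + 1)
between tumor and normal samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .io import ClinicalTable, DataError, ExpressionMatrix, GeneSet, ScreenResult

logger = logging.getLogger("irlncpair")


@dataclass
class CoxFit:
    """One proportional-hazards fit: coefficient, hazard ratio, Wald CI, p.

    Satisfies ``hr == exp(coef)`` and (Wald symmetry on the log scale)
    ``sqrt(hr_low * hr_high) == hr`` up to floating error.
    """

    feature_id: str
    coef: float
    hr: float
    hr_low: float
    hr_high: float
    p_value: float
    n_events: int
    passed: bool = False


def cox_fits_frame(fits: list[CoxFit]) -> pd.DataFrame:
    """Tabulate Cox fits in the conventional ID/coef/HR/CI/p layout."""
    return pd.DataFrame(
        {
            "feature": [f.feature_id for f in fits],
            "coef": [f.coef for f in fits],
            "HR": [f.hr for f in fits],
            "HR.95L": [f.hr_low for f in fits],
            "HR.95H": [f.hr_high for f in fits],
            "p_value": [f.p_value for f in fits],
            "n_events": [f.n_events for f in fits],
            "passed": [f.passed for f in fits],
        }
    ).set_index("feature")


def log2p1(x):
    """log2(x + 1), the pipeline's working scale for expression."""
    return np.log2(np.asarray(x, dtype=float) + 1.0)


# ---------------------------------------------------------------------------
# shared Cox machinery (lifelines, Efron tie handling)
# ---------------------------------------------------------------------------


def fit_cox(
    df: pd.DataFrame, duration_col: str = "os_time", event_col: str = "os_event"
) -> list[CoxFit]:
    """Joint Cox PH fit of every other column of ``df``; Wald CI and p.

    Raises :class:`lifelines.exceptions.ConvergenceError` on failure —
    callers decide whether that is fatal.
    """
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    n_events = int(df[event_col].sum())
    out = []
    for feat in cph.summary.index:
        row = cph.summary.loc[feat]
        out.append(
            CoxFit(
                feature_id=str(feat),
                coef=float(row["coef"]),
                hr=float(np.exp(row["coef"])),
                hr_low=float(np.exp(row["coef lower 95%"])),
                hr_high=float(np.exp(row["coef upper 95%"])),
                p_value=float(row["p"]),
                n_events=n_events,
            )
        )
    return out


def fit_cox_single(
    x: np.ndarray, time: np.ndarray, event: np.ndarray, name: str = "x"
) -> CoxFit:
    """Univariate Cox fit of one covariate."""
    df = pd.DataFrame({"os_time": time, "os_event": event, name: x})
    return fit_cox(df)[0]


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------


def pearson_screen_matrix(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and two-sided p between rows of ``a`` and ``b``.

    p comes from the t transform ``t = r * sqrt((n-2) / (1-r^2))`` with
    n - 2 degrees of freedom.
    """
    n = a.shape[1]
    if n < 3:
        raise DataError("need at least 3 shared samples for correlation")
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az**2).sum(axis=1))
    bsd = np.sqrt((bz**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az @ bz.T) / np.outer(asd, bsd)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return r, p


def identify_irlncrnas(
    lnc: ExpressionMatrix,
    mrna: ExpressionMatrix,
    immune: GeneSet,
    r_min: float = 0.5,
    p_max: float = 0.001,
) -> list[ScreenResult]:
    """Immune co-expression screen.

    A lncRNA passes iff its log-scale Pearson correlation with at least one
    immune gene exceeds ``r_min`` with p below ``p_max``; the
    best-correlated immune partner is recorded.
    """
    if not lnc.sample_ids.equals(mrna.sample_ids):
        raise DataError("lncRNA and mRNA matrices must share the sample axis")
    imm_ids = [g for g in mrna.gene_ids if g in immune]
    if not imm_ids:
        raise DataError("no immune genes present in the mRNA matrix")
    la = log2p1(lnc.values.to_numpy())
    ia = log2p1(mrna.values.loc[imm_ids].to_numpy())
    r, p = pearson_screen_matrix(la, ia)
    hit = (r > r_min) & (p < p_max)
    best = np.argmax(r, axis=1)
    results = []
    for i, g in enumerate(lnc.gene_ids):
        j = best[i]
        results.append(
            ScreenResult(
                feature_id=g,
                statistic=float(r[i, j]),
                p_value=float(p[i, j]),
                effect=float(r[i, j]),
                passed=bool(hit[i].any()),
                partner=imm_ids[j],
            )
        )
    logger.info(
        "immune co-expression screen: %d/%d lncRNAs passed (r > %g, p < %g)",
        sum(x.passed for x in results), len(results), r_min, p_max,
    )
    return results


def differential_screen(
    lnc: ExpressionMatrix, logfc_min: float = 2.0, p_max: float = 0.05
) -> list[ScreenResult]:
    """Tumor-vs-normal differential screen on log2(x + 1) values.

    logFC is the tumor-minus-normal difference of mean log2(x + 1); p is a
    two-sided Wilcoxon rank-sum test on the log values; a gene passes iff
    |logFC| > ``logfc_min`` and p < ``p_max``. Direction (up/down in tumor)
    is recorded.
    """
    tumor = lnc.tumor_samples()
    normal = lnc.normal_samples()
    if len(tumor) < 2 or len(normal) < 2:
        raise DataError("differential screen needs >= 2 samples per class")
    lt = log2p1(lnc.values[tumor].to_numpy())
    ln = log2p1(lnc.values[normal].to_numpy())
    logfc = lt.mean(axis=1) - ln.mean(axis=1)
    stat, p = stats.ranksums(lt, ln, axis=1)
    results = []
    for i, g in enumerate(lnc.gene_ids):
        results.append(
            ScreenResult(
                feature_id=g,
                statistic=float(stat[i]),
                p_value=float(p[i]),
                effect=float(logfc[i]),
                passed=bool(abs(logfc[i]) > logfc_min and p[i] < p_max),
                direction="up" if logfc[i] > 0 else "down",
            )
        )
    n_up = sum(r.passed and r.direction == "up" for r in results)
    n_down = sum(r.passed and r.direction == "down" for r in results)
    logger.info(
        "differential screen: %d/%d passed (|logFC| > %g, p < %g; %d up, %d down)",
        n_up + n_down, len(results), logfc_min, p_max, n_up, n_down,
    )
    return results


def unicox_screen(
    lnc: ExpressionMatrix, clin: ClinicalTable, p_max: float = 0.05
) -> list[CoxFit]:
    """Univariate Cox screen of each lncRNA's log2(x + 1) expression.

    Tumor samples are joined to the clinical table; non-converging features
    are flagged (NaN statistics, not passed) and excluded, not fatal.
    """
    shared = [s for s in lnc.tumor_samples() if s in clin.sample_ids]
    sub = clin.data.loc[shared]
    if int(sub["os_event"].sum()) < 10:
        raise DataError("univariate Cox screen needs >= 10 observed events")
    time = sub["os_time"].to_numpy()
    event = sub["os_event"].to_numpy()
    expr = log2p1(lnc.values[shared].to_numpy())
    fits = []
    n_failed = 0
    for i, g in enumerate(lnc.gene_ids):
        try:
            fit = fit_cox_single(expr[i], time, event, name=str(g))
        except (ConvergenceError, ValueError):
            n_failed += 1
            fits.append(CoxFit(str(g), np.nan, np.nan, np.nan, np.nan, np.nan,
                               int(event.sum()), passed=False))
            continue
        fit.passed = fit.p_value < p_max
        fits.append(fit)
    if n_failed:
        logger.warning("univariate Cox screen: %d feature(s) failed to converge", n_failed)
    logger.info(
        "univariate Cox screen: %d/%d passed (p < %g)",
        sum(f.passed for f in fits), len(fits), p_max,
    )
    return fits


def core_set(de: list[ScreenResult], risk: list[CoxFit]) -> GeneSet:
    """Intersection of the differential and survival screens' passing genes."""
    if not de or not risk:
        raise DataError("both screen result lists must be non-empty")
    de_pass = {r.feature_id for r in de if r.passed}
    risk_pass = {f.feature_id for f in risk if f.passed}
    core = de_pass & risk_pass
    if not core:
        raise DataError(
            "differential and survival screens share no genes; "
            "consider relaxing thresholds"
        )
    logger.info(
        "core set: %d genes (DE %d ∩ risk %d)", len(core), len(de_pass), len(risk_pass)
    )
    return GeneSet("core_irlncRNA", frozenset(core))
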