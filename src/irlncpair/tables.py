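"""Internal-consistency verification of printed Cox model tables.

A multivariate Cox table in the conventional ID/coef/HR/HR.95L/HR.95H/p
layout is internally redundant: HR = exp(coef), HR is the geometric mean
of its Wald CI bounds, and the two-sided p follows from coef and the
CI-implied standard error, p = 2 * Phi(-|coef| / SE) with
SE = (ln HR.95H - ln HR.95L) / (2 * 1.96). ``verify_table`` recomputes all
three redundancies row by row.

The package ships the published 11-pair and 11-gene colon-cancer
irlncRNA-signature tables as reference fixtures
(:func:`load_reference_table`).
"""

from __future__ import annotations

from importlib import resources
from math import floor, log10

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError

#: normal quantile used for the 95% Wald interval
Z95 = stats.norm.ppf(0.975)

_REFERENCE_TABLES = {
    "pair": "pair_risk_model.tsv",
    "expression": "expression_risk_model.tsv",
}


def load_reference_table(kind: str) -> pd.DataFrame:
    """Load a shipped reference Cox table ("pair" or "expression")."""
    try:
        fname = _REFERENCE_TABLES[kind]
    except KeyError:
        raise DataError(f"unknown reference table {kind!r}") from None
    with resources.files("irlncpair.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0 or not np.isfinite(x):
        return x
    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


def verify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute the redundancies of a printed Cox table.

    Expects columns coef, HR, HR.95L, HR.95H and a p-value column (any of
    ``p_value``/``p value``/``p``). Returns per-row relative errors of
    exp(coef) and of the CI geometric mean against the printed HR, the
    recomputed Wald p, and whether it matches the printed p to two
    significant figures.
    """
    cols = {c.lower().replace(" ", "_"): c for c in table.columns}
    pcol = next((cols[k] for k in ("p_value", "p", "pvalue") if k in cols), None)
    need = ("coef", "hr", "hr.95l", "hr.95h")
    if pcol is None or any(k not in cols for k in need):
        raise DataError("table must have coef, HR, HR.95L, HR.95H and p columns")
    coef = table[cols["coef"]].to_numpy(float)
    hr = table[cols["hr"]].to_numpy(float)
    lo = table[cols["hr.95l"]].to_numpy(float)
    hi = table[cols["hr.95h"]].to_numpy(float)
    p = table[pcol].to_numpy(float)

    hr_rel_err = np.abs(np.exp(coef) - hr) / hr
    geo = np.sqrt(lo * hi)
    geo_rel_err = np.abs(geo - hr) / hr
    se = (np.log(hi) - np.log(lo)) / (2.0 * Z95)
    p_recomputed = 2.0 * stats.norm.sf(np.abs(coef) / se)
    p_match = np.array(
        [round_sig(a, 2) == round_sig(b, 2) for a, b in zip(p_recomputed, p)]
    )
    return pd.DataFrame(
        {
            "hr_rel_err": hr_rel_err,
            "ci_geomean_rel_err": geo_rel_err,
            "se_implied": se,
            "p_recomputed": p_recomputed,
            "p_printed": p,
            "p_match_2sig": p_match,
        },
        index=table.index,
    )
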