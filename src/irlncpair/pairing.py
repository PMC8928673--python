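"""The 0-or-1 pair-indicator matrix over core lncRNAs.

For an ordered gene pair (A, B) and a sample, the indicator is 1 iff A's
expression strictly exceeds B's in that sample (ties score 0). Because only
the within-sample ordering matters, the matrix is invariant to any
per-sample monotone transform of expression — the property that makes
pair signatures portable across normalization schemes and platforms.

A pair is a *valid match* only when its indicator is neither quasi-constant
0 nor quasi-constant 1: the fraction of samples scoring 1 must lie strictly
inside (freq_min, 1 - freq_min), default (0.2, 0.8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import DataError, ExpressionMatrix

logger = logging.getLogger("irlncpair")

PAIR_SEP = "|"


def pair_id(gene_a: str, gene_b: str) -> str:
    return f"{gene_a}{PAIR_SEP}{gene_b}"


def parse_pair_id(pid: str) -> tuple[str, str]:
    a, b = pid.split(PAIR_SEP)
    return a, b


@dataclass
class PairMatrix:
    """Binary pairs x samples indicator matrix with validity bookkeeping.

    ``pairs`` lists each unordered pair once in canonical (lexicographic)
    orientation; ``indicators`` rows are indexed by ``"A|B"`` IDs;
    ``freq1`` is the per-pair fraction of samples scoring 1; ``valid``
    flags pairs inside the informative-frequency window. ``expression``
    keeps the sample-aligned expression the matrix was built from so model
    pairs can be re-evaluated in their fitted orientation.
    """

    pairs: list
    indicators: pd.DataFrame
    freq1: pd.Series
    valid: pd.Series
    freq_min: float
    expression: pd.DataFrame

    @property
    def sample_ids(self) -> pd.Index:
        return self.indicators.columns

    def valid_indicators(self) -> pd.DataFrame:
        """Rows of valid pairs only (what goes downstream)."""
        return self.indicators.loc[self.valid.to_numpy()]


def indicator_row(expression: pd.DataFrame, gene_a: str, gene_b: str) -> np.ndarray:
    """0/1 vector over samples: 1 iff expression(gene_a) > expression(gene_b)."""
    for g in (gene_a, gene_b):
        if g not in expression.index:
            raise DataError(f"gene {g!r} absent from expression matrix")
    return (
        expression.loc[gene_a].to_numpy() > expression.loc[gene_b].to_numpy()
    ).astype(np.int8)


def build_pair_matrix(
    core: ExpressionMatrix | pd.DataFrame,
    freq_min: float = 0.2,
    samples=None,
) -> PairMatrix:
    """Enumerate all unordered gene pairs and score the 0/1 indicators.

    Parameters
    ----------
    core
        Expression restricted to the core gene set (k genes yield
        k(k-1)/2 candidate pairs).
    freq_min
        Validity window half-width: a pair is valid iff
        ``freq_min < freq1 < 1 - freq_min``.
    samples
        Optional sample subset over which indicators and frequencies are
        computed (the modeling cohort, typically tumor samples with
        clinical follow-up).
    """
    values = core.values if isinstance(core, ExpressionMatrix) else core
    if samples is not None:
        values = values[list(samples)]
    if values.shape[0] < 2:
        raise DataError("need at least 2 genes to build pairs")
    if values.shape[1] < 1:
        raise DataError("need at least 1 sample to build pairs")
    if not 0 <= freq_min < 0.5:
        raise DataError("freq_min must lie in [0, 0.5)")

    genes = sorted(map(str, values.index))
    arr = values.loc[genes].to_numpy()
    pos = {g: i for i, g in enumerate(genes)}
    pairs = list(combinations(genes, 2))  # lexicographic canonical orientation
    rows = np.empty((len(pairs), arr.shape[1]), dtype=np.int8)
    for k, (a, b) in enumerate(pairs):
        rows[k] = arr[pos[a]] > arr[pos[b]]
    ids = [pair_id(a, b) for a, b in pairs]
    indicators = pd.DataFrame(rows, index=ids, columns=values.columns)
    freq1 = pd.Series(rows.mean(axis=1), index=ids)
    valid = (freq1 > freq_min) & (freq1 < 1.0 - freq_min)
    logger.info(
        "pair matrix: %d candidate pairs from %d genes; %d valid "
        "(%g < freq1 < %g)",
        len(pairs), len(genes), int(valid.sum()), freq_min, 1 - freq_min,
    )
    return PairMatrix(
        pairs=pairs,
        indicators=indicators,
        freq1=freq1,
        valid=valid,
        freq_min=freq_min,
        expression=values.loc[genes],
    )


def pair_indicators_for_model(pm: PairMatrix, model_pairs: list) -> pd.DataFrame:
    """Indicators for a fitted signature, in the model's stated orientation.

    ``model_pairs`` are (gene_a, gene_b) tuples exactly as fitted; the
    returned rows are computed from the underlying expression regardless of
    the canonical storage orientation, so a model pair stored flipped comes
    back complemented at non-tied samples.
    """
    rows = []
    ids = []
    for a, b in model_pairs:
        rows.append(indicator_row(pm.expression, a, b))
        ids.append(pair_id(a, b))
    return pd.DataFrame(np.array(rows), index=ids, columns=pm.sample_ids)


def write_pair_matrix(pm: PairMatrix, path, sidecar=None) -> None:
    """Serialize indicators as TSV; freq1/validity as a JSON sidecar."""
    pm.indicators.to_csv(path, sep="\t", index_label="pair")
    if sidecar is not None:
        import json

        meta = {
            "freq_min": pm.freq_min,
            "freq1": {k: float(v) for k, v in pm.freq1.items()},
            "valid": {k: bool(v) for k, v in pm.valid.items()},
        }
        with open(sidecar, "w") as fh:
            json.dump(meta, fh, indent=1)
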