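"""Shared data types and readers/writers for the standard file formats.

The pipeline works from four inputs: a genes x samples expression matrix
(TSV, non-negative normalized values), a GTF annotation used to split
lncRNAs from protein-coding mRNAs, a plain-text immune-gene list, and a
clinical table with overall-survival time/event plus ordinal covariates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("irlncpair")

LNCRNA = "lncRNA"
PROTEIN_CODING = "protein_coding"
OTHER = "other"

#: substrings of a GTF biotype value that mark a gene as long non-coding
_LNC_BIOTYPE_PATTERNS = ("lncrna", "lincrna", "antisense")

# TCGA barcode sample-type codes: 01-09 tumor, 10-19 normal
_TCGA_SAMPLE_RE = re.compile(r"^TCGA-[^-]+-[^-]+-(\d{2})")


class DataError(ValueError):
    """Invalid or inconsistent input data."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with per-gene biotype and per-sample class.

    Parameters
    ----------
    values
        Non-negative expression (normalized units, e.g. FPKM/TPM); rows are
        genes, columns are samples.
    gene_biotype
        Per-gene label in {"lncRNA", "protein_coding", "other"}, indexed
        like ``values.index``.
    sample_class
        Per-sample label in {"tumor", "normal"}, indexed like
        ``values.columns``.
    """

    values: pd.DataFrame
    gene_biotype: pd.Series
    sample_class: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DataError(f"duplicate gene ID: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise DataError(f"duplicate sample ID: {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataError("expression values must be numeric")
        if np.nanmin(arr) < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise DataError(
                f"negative expression at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        self.gene_biotype = self.gene_biotype.reindex(self.values.index)
        if self.gene_biotype.isna().any():
            missing = self.gene_biotype.index[self.gene_biotype.isna()][0]
            raise DataError(f"gene without biotype: {missing!r}")
        self.sample_class = self.sample_class.reindex(self.values.columns)
        if self.sample_class.isna().any():
            missing = self.sample_class.index[self.sample_class.isna()][0]
            raise DataError(f"sample without class label: {missing!r}")
        bad = set(self.sample_class.unique()) - {"tumor", "normal"}
        if bad:
            raise DataError(f"unknown sample class label(s): {sorted(bad)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(
            self.values.loc[genes], self.gene_biotype.loc[genes], self.sample_class
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(samples)], self.gene_biotype, self.sample_class[list(samples)]
        )

    def tumor_samples(self) -> pd.Index:
        return self.sample_ids[self.sample_class.to_numpy() == "tumor"]

    def normal_samples(self) -> pd.Index:
        return self.sample_ids[self.sample_class.to_numpy() == "normal"]


@dataclass
class ClinicalTable:
    """Per-sample overall-survival time/event and clinical covariates.

    ``data`` is indexed by sample ID with columns ``os_time`` (positive),
    ``os_event`` (0 censored / 1 death) and optional ordinal covariates
    ``age``, ``stage``, ``t_stage``, ``n_stage``, ``m_stage`` (NaN allowed).
    ``time_unit`` declares the unit of ``os_time`` ("days" or "years") so
    ROC horizons can be stated explicitly.
    """

    data: pd.DataFrame
    time_unit: str = "days"

    COVARIATES = ("age", "stage", "t_stage", "n_stage", "m_stage")

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DataError(f"duplicate sample ID in clinical table: {dup!r}")
        if not {"os_time", "os_event"} <= set(self.data.columns):
            raise DataError("clinical table requires os_time and os_event columns")
        if (self.data["os_time"] <= 0).any() or self.data["os_time"].isna().any():
            raise DataError("os_time must be positive and non-missing")
        if not self.data["os_event"].isin([0, 1]).all():
            raise DataError("os_event must be coded 0/1")
        if self.time_unit not in ("days", "years"):
            raise DataError(f"unknown time unit {self.time_unit!r}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def subset(self, samples) -> "ClinicalTable":
        keep = [s for s in samples if s in self.data.index]
        return ClinicalTable(self.data.loc[keep], self.time_unit)

    def in_years(self) -> "ClinicalTable":
        """Return a copy with os_time converted to years (365.25 d/yr)."""
        if self.time_unit == "years":
            return ClinicalTable(self.data.copy(), "years")
        out = self.data.copy()
        out["os_time"] = out["os_time"] / 365.25
        return ClinicalTable(out, "years")


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty set of gene identifiers."""

    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise DataError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene) -> bool:
        return gene in self.members


@dataclass
class ScreenResult:
    """Outcome of one feature in one screening stage."""

    feature_id: str
    statistic: float
    p_value: float
    effect: float
    passed: bool
    partner: str | None = None  # best-correlated immune gene, where relevant
    direction: str | None = None  # "up"/"down" in tumor, where relevant


def screen_results_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Tabulate a list of :class:`ScreenResult` as a DataFrame."""
    return pd.DataFrame(
        {
            "feature": [r.feature_id for r in results],
            "statistic": [r.statistic for r in results],
            "effect": [r.effect for r in results],
            "p_value": [r.p_value for r in results],
            "passed": [r.passed for r in results],
            "partner": [r.partner for r in results],
            "direction": [r.direction for r in results],
        }
    ).set_index("feature")


# ---------------------------------------------------------------------------
# GTF / gene list parsing
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def classify_biotype(raw: str) -> str:
    """Map a raw GTF biotype string onto {lncRNA, protein_coding, other}."""
    low = raw.lower()
    if any(pat in low for pat in _LNC_BIOTYPE_PATTERNS):
        return LNCRNA
    if low == "protein_coding":
        return PROTEIN_CODING
    return OTHER


def read_gtf_biotypes(path) -> dict:
    """Extract ``gene_id -> biotype`` from a GTF file.

    Accepts either a ``gene_type`` or ``gene_biotype`` attribute key; also
    records the ``gene_name`` alias so expression rows keyed by symbol
    resolve.
    """
    biotypes: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            attrs = dict(_ATTR_RE.findall(parts[8]))
            raw = attrs.get("gene_type") or attrs.get("gene_biotype")
            if raw is None:
                continue
            bt = classify_biotype(raw)
            for key in ("gene_id", "gene_name"):
                gid = attrs.get(key)
                if gid and gid not in biotypes:
                    biotypes[gid] = bt
    return biotypes


def read_gene_list(path, name: str = "immune") -> GeneSet:
    """Read a one-identifier-per-line gene list."""
    with open(path) as fh:
        members = {line.strip() for line in fh if line.strip()}
    return GeneSet(name, members)


def parse_tcga_sample_class(sample_id: str) -> str | None:
    """Tumor/normal from a TCGA barcode sample-type code (01 tumor, 11 normal)."""
    m = _TCGA_SAMPLE_RE.match(sample_id)
    if not m:
        return None
    code = int(m.group(1))
    if 1 <= code <= 9:
        return "tumor"
    if 10 <= code <= 19:
        return "normal"
    return None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _check_unique_header(path) -> list:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set = set()
    for sid in header:
        if sid in seen:
            raise DataError(f"duplicate sample ID in header: {sid!r}")
        seen.add(sid)
    return header


def read_expression(path, annotation, labels=None) -> ExpressionMatrix:
    """Read a genes x samples expression TSV plus a GTF annotation.

    Parameters
    ----------
    path
        TSV with a header row of sample IDs and one gene per row.
    annotation
        GTF file whose records carry ``gene_id`` and a biotype attribute.
    labels
        Path to a two-column (sample, class) TSV, or a mapping, or ``None``
        to derive tumor/normal from TCGA-style barcodes.

    Genes absent from the GTF are labeled biotype "other" with a warning.
    """
    _check_unique_header(path)
    values = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise DataError(f"duplicate gene ID: {dup!r}")
    non_num = values.columns[
        [not np.issubdtype(dt, np.number) for dt in values.dtypes]
    ]
    if len(non_num):
        col = non_num[0]
        coerced = pd.to_numeric(values[col], errors="coerce")
        row = values.index[coerced.isna()][0]
        raise DataError(f"non-numeric expression value at gene {row!r}, sample {col!r}")

    biotypes = read_gtf_biotypes(annotation)
    gene_biotype = pd.Series(
        [biotypes.get(g, OTHER) for g in values.index], index=values.index
    )
    unannotated = int((~values.index.isin(biotypes)).sum())
    if unannotated:
        logger.warning(
            "%d gene(s) absent from the GTF; labeled biotype 'other'", unannotated
        )

    if labels is None:
        classes = {}
        for sid in values.columns:
            cls = parse_tcga_sample_class(sid)
            if cls is None:
                raise DataError(
                    f"cannot derive tumor/normal for sample {sid!r}; provide a label file"
                )
            classes[sid] = cls
        sample_class = pd.Series(classes)
    elif isinstance(labels, (str,)) or hasattr(labels, "__fspath__"):
        lab = pd.read_csv(labels, sep="\t", header=None, index_col=0)
        sample_class = lab.iloc[:, 0]
    else:
        sample_class = pd.Series(dict(labels))

    return ExpressionMatrix(values, gene_biotype, sample_class)


def write_expression(m: ExpressionMatrix, path) -> None:
    """Write the expression values as TSV (full float precision)."""
    m.values.to_csv(path, sep="\t", float_format="%.17g")


def split_by_biotype(m: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Partition into (lncRNA, protein-coding) matrices; drop "other" genes."""
    bt = m.gene_biotype
    lnc_ids = m.gene_ids[bt.to_numpy() == LNCRNA]
    mrna_ids = m.gene_ids[bt.to_numpy() == PROTEIN_CODING]
    n_other = len(m.gene_ids) - len(lnc_ids) - len(mrna_ids)
    if n_other:
        logger.info("dropped %d gene(s) with biotype 'other'", n_other)
    if len(lnc_ids) == 0:
        raise DataError("no lncRNA genes after biotype split; pipeline cannot proceed")
    lnc = ExpressionMatrix(m.values.loc[lnc_ids], bt.loc[lnc_ids], m.sample_class)
    mrna = ExpressionMatrix(m.values.loc[mrna_ids], bt.loc[mrna_ids], m.sample_class)
    return lnc, mrna


_DEFAULT_EVENT_MAP = {
    "0": 0, "1": 1, "alive": 0, "dead": 1, "living": 0, "deceased": 1,
    "censored": 0, "event": 1,
}

_STAGE_RE = re.compile(r"(?:stage\s*)?([ivx]+|[0-9]+)\s*[a-c]?$", re.IGNORECASE)
_ROMAN = {"i": 1, "ii": 2, "iii": 3, "iv": 4}


def normalize_stage(value) -> float:
    """Normalize stage-like strings ("Stage IIa", "T3", "II") to an ordinal.

    Returns NaN for missing/unparseable values.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip().lower()
    if not s or s in ("na", "nan", "nx", "tx", "mx", "unknown", "not reported"):
        return np.nan
    try:
        return float(s)  # already-normalized ordinal
    except ValueError:
        pass
    s = re.sub(r"^[tnm]", "", s)  # "T3" -> "3"
    m = _STAGE_RE.match(s)
    if not m:
        return np.nan
    tok = m.group(1).lower()
    if tok in _ROMAN:
        return float(_ROMAN[tok])
    try:
        return float(int(tok))
    except ValueError:
        return np.nan


def read_clinical(
    path,
    time_unit: str = "days",
    event_map: dict | None = None,
    column_map: dict | None = None,
) -> ClinicalTable:
    """Read a clinical TSV into a :class:`ClinicalTable`.

    Rows with non-positive or missing time/event are dropped (count logged);
    stage-like covariates are normalized to ordinals; event strings are
    recoded via ``event_map`` (defaults cover alive/dead).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    cmap = {"sample": "sample_id", "time": "os_time", "event": "os_event"}
    if column_map:
        cmap.update(column_map)
    raw = raw.rename(columns=cmap)
    if "sample_id" not in raw.columns:
        raw = raw.rename(columns={raw.columns[0]: "sample_id"})
    if not {"os_time", "os_event"} <= set(raw.columns):
        raise DataError("clinical table requires time and event columns")
    raw = raw.set_index("sample_id")

    emap = dict(_DEFAULT_EVENT_MAP)
    if event_map:
        emap.update({str(k).lower(): v for k, v in event_map.items()})
    os_time = pd.to_numeric(raw["os_time"], errors="coerce")
    os_event = raw["os_event"].astype(str).str.strip().str.lower().map(emap)

    usable = (os_time > 0) & os_event.notna()
    n_drop = int((~usable).sum())
    if n_drop:
        logger.info("dropped %d clinical row(s) with unusable time/event", n_drop)
    if not usable.any():
        raise DataError("no usable clinical rows (positive time, valid event)")

    out = pd.DataFrame(
        {"os_time": os_time[usable], "os_event": os_event[usable].astype(int)}
    )
    if "age" in raw.columns:
        out["age"] = pd.to_numeric(raw.loc[usable, "age"], errors="coerce")
    for col in ("stage", "t_stage", "n_stage", "m_stage"):
        if col in raw.columns:
            out[col] = raw.loc[usable, col].map(normalize_stage)
    return ClinicalTable(out, time_unit)


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.data.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")
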