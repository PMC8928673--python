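"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the shape of a bulk tumor/normal expression study
with survival follow-up: two sample classes, immune-gene/lncRNA
co-expression, tumor-vs-normal differential lncRNAs, and survival times
whose hazard depends on planted within-sample expression-order pair
indicators through a proportional-hazards model.

Expression is log-normal: each gene's log2 expression is Gaussian around a
gene-specific baseline, and an immune-coupled lncRNA shares a latent factor
with one immune gene so that the population Pearson correlation on the log
scale equals ``latent_coupling / sqrt(latent_coupling**2 + noise_sd**2)``.
Values are exported on the natural (exponentiated) scale, all positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable, DataError, ExpressionMatrix, GeneSet, LNCRNA, PROTEIN_CODING


def _default_planted_pairs() -> list:
    return [
        ("LNC0000", "LNC0001", 1.0),
        ("LNC0002", "LNC0003", -1.0),
        ("LNC0004", "LNC0005", 1.0),
    ]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Defaults mirror the cohort shape the pipeline targets: 473 tumor and 41
    adjacent-normal samples and a 2,483-gene immune panel, with a
    desk-scale transcript panel (300 lncRNAs, 3,000 mRNAs). Survival times
    are exponential with ``baseline_hazard`` per year, censored uniformly
    on (0, ``censor_max``) years.
    """

    n_tumor: int = 473
    n_normal: int = 41
    n_lnc: int = 300
    n_mrna: int = 3000
    n_immune: int = 2483
    n_irlnc_true: int = 30  # lncRNAs coupled to an immune gene
    latent_coupling: float = 0.9
    noise_sd: float = 0.5
    n_de_true: int = 20  # lncRNAs shifted in tumor samples
    de_log2fc: float = 3.0
    planted_pairs: list = field(default_factory=_default_planted_pairs)
    baseline_hazard: float = 0.08  # events per year
    censor_max: float = 12.0  # years
    baseline: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal", "n_lnc", "n_mrna", "n_immune"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")
        if not 0 < self.latent_coupling <= 1:
            raise DataError("latent_coupling must be in (0, 1]")
        if self.n_immune > self.n_mrna:
            raise DataError("n_immune cannot exceed n_mrna")
        lnc_ids = set(self._lnc_ids())
        for a, b, _beta in self.planted_pairs:
            if a == b:
                raise DataError(f"planted pair members must differ: {a!r}")
            for g in (a, b):
                if g not in lnc_ids:
                    raise DataError(f"planted pair references unknown lncRNA {g!r}")

    def _lnc_ids(self) -> list:
        return [f"LNC{i:04d}" for i in range(self.n_lnc)]

    def _mrna_ids(self) -> list:
        return [f"MRNA{i:04d}" for i in range(self.n_mrna)]

    def _immune_ids(self) -> list:
        return self._mrna_ids()[: self.n_immune]


def ground_truth(cfg: SimulationConfig) -> dict:
    """Deterministic planted-structure labels for a config.

    Returns a dict with ``immune_coupled`` (lncRNA -> immune partner),
    ``de_genes`` (list), and ``planted_pairs`` (list of (a, b, beta));
    consistent with :func:`simulate_cohort` under the same seed.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    lnc = cfg._lnc_ids()
    immune = cfg._immune_ids()
    coupled = lnc[: cfg.n_irlnc_true]
    partners = rng.choice(len(immune), size=len(coupled), replace=True)
    return {
        "immune_coupled": {g: immune[p] for g, p in zip(coupled, partners)},
        "de_genes": lnc[: cfg.n_de_true],
        "planted_pairs": [tuple(p) for p in cfg.planted_pairs],
    }


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, GeneSet]:
    """Draw one cohort: expression matrix, clinical table, immune gene set."""
    truth = ground_truth(cfg)
    rng = np.random.default_rng([cfg.seed, 2])

    lnc_ids = cfg._lnc_ids()
    mrna_ids = cfg._mrna_ids()
    immune_ids = cfg._immune_ids()
    n_samples = cfg.n_tumor + cfg.n_normal
    sample_ids = [f"TUM{i:04d}" for i in range(cfg.n_tumor)] + [
        f"NRM{i:04d}" for i in range(cfg.n_normal)
    ]
    is_tumor = np.array([True] * cfg.n_tumor + [False] * cfg.n_normal)

    # gene-specific log2 baselines; planted-pair members share a baseline so
    # the pair's indicator frequency sits near 1/2
    mu_lnc = rng.uniform(3.0, 8.0, size=cfg.n_lnc)
    mu_mrna = rng.uniform(3.0, 8.0, size=cfg.n_mrna)
    lnc_pos = {g: i for i, g in enumerate(lnc_ids)}
    for a, b, _beta in cfg.planted_pairs:
        mu_lnc[lnc_pos[b]] = mu_lnc[lnc_pos[a]]

    # mRNA log2 expression: unit-variance latent per gene
    latent = rng.standard_normal((cfg.n_mrna, n_samples))
    log_mrna = mu_mrna[:, None] + latent

    # lncRNAs: coupled genes share the immune partner's latent factor
    log_lnc = np.empty((cfg.n_lnc, n_samples))
    imm_index = {g: i for i, g in enumerate(mrna_ids)}
    coupled = truth["immune_coupled"]
    for i, g in enumerate(lnc_ids):
        if g in coupled:
            f = latent[imm_index[coupled[g]]]
            log_lnc[i] = (
                mu_lnc[i]
                + cfg.latent_coupling * f
                + cfg.noise_sd * rng.standard_normal(n_samples)
            )
        else:
            log_lnc[i] = mu_lnc[i] + rng.standard_normal(n_samples)

    # tumor-vs-normal shift for DE lncRNAs
    for g in truth["de_genes"]:
        log_lnc[lnc_pos[g], is_tumor] += cfg.de_log2fc

    values = pd.DataFrame(
        np.vstack([2.0 ** log_lnc, 2.0 ** log_mrna]),
        index=lnc_ids + mrna_ids,
        columns=sample_ids,
    )
    biotype = pd.Series(
        [LNCRNA] * cfg.n_lnc + [PROTEIN_CODING] * cfg.n_mrna, index=values.index
    )
    sample_class = pd.Series(
        np.where(is_tumor, "tumor", "normal"), index=values.columns
    )
    expr = ExpressionMatrix(values, biotype, sample_class)

    # survival on tumor samples: hazard scales with planted pair indicators,
    # computed exactly as the 0/1 pair matrix defines them (A > B per sample)
    tumor_cols = np.array(sample_ids)[is_tumor]
    lp = np.zeros(cfg.n_tumor)
    for a, b, beta in cfg.planted_pairs:
        ind = (
            values.loc[a, tumor_cols].to_numpy()
            > values.loc[b, tumor_cols].to_numpy()
        ).astype(float)
        lp += beta * ind
    rate = cfg.baseline_hazard * np.exp(lp)
    e = rng.exponential(1.0, size=cfg.n_tumor)
    if cfg.baseline == "weibull":
        t_event = (e / rate) ** (1.0 / cfg.weibull_shape)
    else:
        t_event = e / rate
    c = rng.uniform(0.0, cfg.censor_max, size=cfg.n_tumor)
    os_time = np.minimum(t_event, c)
    os_event = (t_event <= c).astype(int)
    os_time = np.maximum(os_time, 1e-8)  # guard the positive-time invariant

    clin = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "age": np.round(rng.normal(65, 10, size=cfg.n_tumor)),
            "stage": rng.integers(1, 5, size=cfg.n_tumor).astype(float),
            "t_stage": rng.integers(1, 5, size=cfg.n_tumor).astype(float),
            "n_stage": rng.integers(0, 3, size=cfg.n_tumor).astype(float),
            "m_stage": rng.integers(0, 2, size=cfg.n_tumor).astype(float),
        },
        index=pd.Index(tumor_cols, name="sample_id"),
    )
    clinical = ClinicalTable(clin, time_unit="years")
    immune = GeneSet("immune", frozenset(immune_ids))
    return expr, clinical, immune
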