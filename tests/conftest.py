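import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from irlncpair import (
    ClinicalTable,
    ExpressionMatrix,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture
def tiny_expression() -> ExpressionMatrix:
    """3 genes (2 lncRNA, 1 coding) x 4 samples (3 tumor, 1 normal)."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [5.0, 5.0, 5.0, 5.0]],
        index=["LNC_A", "LNC_B", "PC_C"],
        columns=["s1", "s2", "s3", "s4"],
    )
    biotype = pd.Series(
        ["lncRNA", "lncRNA", "protein_coding"], index=values.index
    )
    sample_class = pd.Series(
        ["tumor", "tumor", "tumor", "normal"], index=values.columns
    )
    return ExpressionMatrix(values, biotype, sample_class)


def make_clinical(times, events, index=None, **covs) -> ClinicalTable:
    idx = index if index is not None else [f"s{i}" for i in range(len(times))]
    df = pd.DataFrame({"os_time": times, "os_event": events}, index=idx)
    for k, v in covs.items():
        df[k] = v
    return ClinicalTable(df, time_unit="years")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_tumor=250, n_normal=40, n_lnc=60, n_mrna=200, n_immune=100,
        n_irlnc_true=20, n_de_true=14, seed=11,
    )
    expr, clin, immune = simulate_cohort(cfg)
    return cfg, expr, clin, immune


def random_survival(rng, n, event_frac=0.7):
    """Marker-independent survival data for null simulations."""
    t = rng.exponential(5.0, size=n)
    c = rng.uniform(0, 5.0 / event_frac, size=n)
    return np.minimum(t, c), (t <= c).astype(int)
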