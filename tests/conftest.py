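import numpy as np
import pandas as pd
import pytest

from graftage.io import SampleTable
from graftage.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One study-scale cohort (n=28) under default study conditions."""
    return simulate_cohort(SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def small_config():
    """A miniature structure for fast end-to-end runs."""
    return SimulationConfig(
        n_subjects=24, n_clock_cpgs=60, n_genes=60, cpgs_per_promoter=2,
        n_gene_sets=10, genes_per_set=8, seed=5,
    )


def make_survival_table(entry, time, event, x=None, batch=None) -> SampleTable:
    """Minimal valid sample sheet around a survival triple, for Cox tests."""
    n = len(time)
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "donor_age": np.full(n, 40.0),
        "recipient_age": np.full(n, 55.0),
        "pgd": np.zeros(n, dtype=bool),
        "batch": batch if batch is not None else ["b1"] * n,
        "entry_time": np.asarray(entry, dtype=float),
        "event_time": np.asarray(time, dtype=float),
        "event": np.asarray(event, dtype=bool),
    })
    if x is not None:
        df["x"] = np.asarray(x, dtype=float)
    return SampleTable(df)
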