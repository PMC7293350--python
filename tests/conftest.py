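import warnings

import numpy as np
import pandas as pd
import pytest

from tmetyper import SimulationConfig, generate_cohort
from tmetyper.preprocess import NormalizedMatrix


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast, clearly separated cohort: 600 genes, 30 tumors/arm."""
    return SimulationConfig(
        n_genes=600,
        n_tumor_per_subtype=(30, 30),
        n_controls=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, name="SYNA")


@pytest.fixture()
def tiny_counts() -> pd.DataFrame:
    """Hand-sized count matrix for normalization arithmetic."""
    return pd.DataFrame(
        {
            "s1": [10, 20, 70],
            "s2": [5, 10, 35],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )


def fpkm_matrix(values: dict, genes=None) -> NormalizedMatrix:
    df = pd.DataFrame(values)
    if genes is not None:
        df.index = pd.Index(genes, name="gene_id")
    return NormalizedMatrix(df, "fpkm")


@pytest.fixture(autouse=True)
def _silence_small_sample_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="small sample")
        yield
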