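import numpy as np
import pandas as pd
import pytest

from crossomics import OmicsMatrix, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A reduced study design that keeps end-to-end tests fast."""
    return SyntheticConfig(
        n_genes=300, n_mirnas=40, frac_diff_genes=0.04, module_size=8,
        n_pathways=8, pathway_size_range=(8, 20), seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size dataset (2000 genes, 5+5) shared across tests."""
    return generate_dataset(SyntheticConfig(seed=5))


@pytest.fixture()
def toy_matrix():
    """A 4-gene, 3+3 matrix with one strongly differential gene."""
    rng = np.random.default_rng(42)
    samples = ["H1", "H2", "H3", "L1", "L2", "L3"]
    vals = rng.normal(5.0, 1.0, size=(4, 6))
    vals[0, :3] += 4.0
    df = pd.DataFrame(vals, index=["gA", "gB", "gC", "gD"], columns=samples)
    groups = pd.Series(["high"] * 3 + ["low"] * 3, index=samples)
    return OmicsMatrix(df, groups)
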