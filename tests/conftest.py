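import numpy as np
import pandas as pd
import pytest

import saltol as st


@pytest.fixture(scope="session")
def small_cfg():
    return st.SimulationConfig(n_accessions=120, n_markers=300, seed=3)


@pytest.fixture(scope="session")
def small_geno(small_cfg):
    return st.simulate_genotypes(small_cfg)


@pytest.fixture(scope="session")
def small_trial(small_cfg, small_geno):
    """(phenotype table, ground truth) for the small default trial."""
    return st.simulate_phenotypes(small_cfg, small_geno)


@pytest.fixture(scope="session")
def noiseless_cfg():
    """All variance components and ratio noise zero: deterministic means."""
    return st.SimulationConfig(
        n_accessions=30, n_markers=40, n_causal=0, seed=5,
        var_genotype=0.0, var_year=0.0, var_treatment=0.0,
        var_gxy=0.0, var_gxl=0.0, var_residual=0.0,
        tolerance_ratio_base=0.8, tolerance_ratio_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_cfg):
    geno = st.simulate_genotypes(noiseless_cfg)
    return st.simulate_phenotypes(noiseless_cfg, geno)


@pytest.fixture()
def toy_index_matrix():
    """Small accession x trait index matrix with off-round values."""
    rng = np.random.default_rng(42)
    data = 100.0 * rng.uniform(0.4, 1.2, size=(12, 5))
    return pd.DataFrame(
        data,
        index=pd.Index([f"S{i + 1}" for i in range(12)], name="accession"),
        columns=["DW", "PH", "TN", "GN", "PW"],
    )
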