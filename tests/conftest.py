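import numpy as np
import pandas as pd
import pytest

from zmeta import SignedZTable, bone_metastasis_scenario, run_pipeline


def make_table(z_by_gene, n_studies=1, label=""):
    z = pd.Series(z_by_gene, dtype=float)
    return SignedZTable.from_series(z, n_studies, label=label)


def random_table(rng, n_genes, label="", scale=1.0):
    genes = [f"G{i:04d}" for i in range(n_genes)]
    z = pd.Series(scale * rng.standard_normal(n_genes), index=genes)
    n = pd.Series(rng.integers(1, 6, size=n_genes), index=genes)
    return SignedZTable.from_series(z, n, label=label)


@pytest.fixture(scope="session")
def small_scenario():
    """One seeded small multi-study collection plus its pipeline result."""
    truth, roles = bone_metastasis_scenario(
        n_genes=2000, n_effect_per_contrast=40, n_studies_per_role=5, seed=11
    )
    result = run_pipeline(
        roles["bone"],
        roles["nonbone"],
        roles["prostate_normal_vs_tumor"],
        roles["localized_vs_metastatic"],
        k=100,
    )
    return truth, roles, result


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
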