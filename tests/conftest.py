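import numpy as np
import pytest

from twinpath import (
    VarianceComponents,
    simulate_expression,
    simulate_univariate_twins,
)


@pytest.fixture(scope="session")
def ae_table_large():
    """2000+2000 pairs under an additive truth a2=0.6, e2=0.4."""
    truth = VarianceComponents(a2=0.6, e2=0.4)
    return simulate_univariate_twins(truth, n_mz=2000, n_dz=2000, seed=20260101)


@pytest.fixture(scope="session")
def clustered_expression():
    """Cluster-structured donor expression matrices with known labels."""
    donors, labels, informative = simulate_expression(
        n_clusters=4,
        n_regions_per_cluster=5,
        n_genes=150,
        effect_size=4.0,
        informative_fraction=0.2,
        inter_donor_corr=0.6,
        seed=42,
    )
    return donors, labels, informative


@pytest.fixture
def small_pairs():
    """8 fixed pairs whose ICC(1,1) was hand-computed from the ANOVA table."""
    return np.array(
        [
            [1.2, 1.4], [2.3, 2.1], [3.1, 2.9], [0.5, 0.8],
            [1.9, 2.2], [2.8, 2.5], [1.1, 0.9], [3.3, 3.6],
        ]
    )
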