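import numpy as np
import pytest

from umclone.simulate import SimulationConfig, generate_sample


@pytest.fixture(scope="session")
def two_cluster_sample():
    """Simulated tumor with a clonal cluster and one subclone at CCF 0.4
    (100 mutations each, depth 100, purity 1, no neutral tail)."""
    cfg = SimulationConfig(
        purity=1.0,
        mean_depth=100,
        n_clonal_mutations=100,
        subclone_ccfs=[0.4],
        subclone_mutation_counts=[100],
        neutral_mu_over_beta=0.0,
        seed=7,
    )
    return generate_sample(cfg)


@pytest.fixture(scope="session")
def canonical_um_sample():
    """Class-2-like tumor: clonal GNAQ with LOH3, subclonal BAP1 at CCF 0.6."""
    cfg = SimulationConfig(
        purity=0.8,
        mean_depth=120,
        n_clonal_mutations=120,
        subclone_ccfs=[0.6],
        subclone_mutation_counts=[90],
        neutral_mu_over_beta=0.0,
        cna_spec=[("LOH3", 1, 0, 0), ("8q+", 2, 1, 0)],
        driver_spec=[("GNAQ", 0), ("BAP1", 1)],
        seed=11,
    )
    return generate_sample(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
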