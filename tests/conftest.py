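import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast synthetic clade shared across tests (seeded)."""
    from cladeprimers.synthetic_pangenome import SimulationConfig, simulate_pangenome

    config = SimulationConfig(
        n_target_genomes=3,
        n_core_genes=3,
        gene_len_codons=(120, 160),
        substitution_prob=0.02,
        n_offtarget_genomes=1,
        planted=(),
        decoy=None,
        seed=7,
    )
    return simulate_pangenome(config)
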