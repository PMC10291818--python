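import numpy as np
import pytest

from polyhekit.simgenome import LTRBurst, SimConfig, generate_study


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_config():
    """A fast, burst-free two-parent simulation used across unit tests."""
    return SimConfig(
        n_chromosomes=1,
        ancestor_length=100_000,
        n_genes=20,
        gene_length=600,
        ltr_bursts=(),
        depth=5.0,
        error_rate=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_parents(tiny_config):
    parent_a, parent_b, truth = generate_study(tiny_config)
    return parent_a, parent_b, truth


@pytest.fixture(scope="session")
def burst_config():
    """Small config with one LTR burst per subgenome."""
    return SimConfig(
        n_chromosomes=1,
        ancestor_length=200_000,
        n_genes=20,
        gene_length=600,
        ltr_bursts=(
            LTRBurst("A", 340_000.0, 20, 5_000, 2_000),
            LTRBurst("B", 50_000.0, 20, 5_000, 2_000),
        ),
        depth=0.0,
        seed=7,
    )
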