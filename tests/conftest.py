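import numpy as np
import pytest

from minichrom.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact but fully featured simulated study (2 contigs, 4 strains)."""
    return SimulationConfig(
        seed=11,
        n_contigs=2,
        contig_length_bp=100_000,
        genes_per_contig=45,
        n_minichromosomes=400,
        long_read_count=300,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_all(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_917)


def random_read(rng: np.random.Generator, length: int, gc: float = 0.3) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.random.default_rng(rng.integers(2**31)).choice(list("ACGT"), size=length, p=p))
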