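import numpy as np
import pytest

from plastichrom.config import SimConfig


@pytest.fixture
def small_cfg() -> SimConfig:
    """A fast configuration for unit tests."""
    return SimConfig(
        seed=7,
        n_promoters=400,
        n_cells=300,
        n_genes=300,
        n_clusters=3,
        program_size=30,
        program_effect=1.0,
    )


def nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial sampler (var = mu + mu^2 * dispersion) for test data."""
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))
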