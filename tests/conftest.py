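import numpy as np
import pytest

from ubshift import ChainTopology, SyntheticSpec, enumerate_states

# Published study conditions for the wild-type triubiquitin chain.
WT_FRACTIONS = np.array([0.76, 0.33, 0.47])
WT_POPULATIONS = np.array([0.28, 0.48, 0.19, 0.05])
K48S_POPULATIONS = np.array([0.33, 0.37, 0.26, 0.04])
TETRA_FRACTIONS = np.array([0.74, 0.53, 0.36, 0.60])


@pytest.fixture(scope="session")
def triub_space():
    return enumerate_states(ChainTopology(3))


@pytest.fixture
def wt_spec():
    """Noise-free synthetic triUb bundle at the wild-type populations."""
    return SyntheticSpec(
        topology=ChainTopology(3),
        true_populations=tuple(WT_POPULATIONS),
        noise_sigma_H=0.0,
        noise_sigma_N=0.0,
        seed=7,
    )


def random_simplex(rng: np.random.Generator, k: int) -> np.ndarray:
    """Uniform point on the k-simplex (flat Dirichlet)."""
    return rng.dirichlet(np.ones(k))
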