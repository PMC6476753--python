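import numpy as np
import pytest

from landres import GenotypeTable, SyntheticConfig


@pytest.fixture
def tiny_table() -> GenotypeTable:
    """Two individuals, two loci — the worked Bray-Curtis example."""
    return GenotypeTable(
        ids=["A", "B"],
        loci=["L1", "L2"],
        calls=np.array([[[1, 1], [2, 3]],
                        [[1, 2], [2, 2]]]),
    )


@pytest.fixture
def small_world_config() -> SyntheticConfig:
    """A fast synthetic world for pipeline-level tests."""
    return SyntheticConfig(
        grid_rows=25, grid_cols=25, n_individuals=30, n_loci=6,
        sex_ratio=0.5, seed=7,
    )


def random_symmetric(rng: np.random.Generator, n: int) -> np.ndarray:
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


@pytest.fixture
def sym_factory():
    return random_symmetric
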