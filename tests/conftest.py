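"""Shared fixtures: random structures and the session-wide synthetic set."""

import numpy as np
import pytest

from qewald.sampling import generate_dataset
from qewald.structures import AtomicStructure


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_structure(rng, n_atoms=None, charge=0, elements=(1, 6, 7, 8, 30),
                     scale=2.5):
    """A random non-degenerate cluster for property tests."""
    if n_atoms is None:
        n_atoms = int(rng.integers(2, 10))
    while True:
        coords = rng.normal(scale=scale, size=(n_atoms, 3))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        if d[np.triu_indices(n_atoms, 1)].min() > 0.7:
            break
    return AtomicStructure(
        elements=rng.choice(elements, size=n_atoms),
        coords=coords,
        total_charge=charge,
    )


@pytest.fixture(scope="session")
def ablation_dataset():
    """The frozen 50-ensemble synthetic data set (generated once per run)."""
    from qewald.protocols import ABLATION_DATASET

    return generate_dataset(seed=7, **ABLATION_DATASET)
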