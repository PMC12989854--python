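from pathlib import Path

import numpy as np
import pytest

from genepace.distances import DistanceTensor
from genepace.simulate import SimulationConfig, simulate_tensor, simulate_yule_tree

TOY_DIR = Path(__file__).parent / "data" / "toy"
TOY_SEED = 20260921


@pytest.fixture(scope="session")
def toy_dir() -> Path:
    return TOY_DIR


@pytest.fixture(scope="session")
def small_tree():
    return simulate_yule_tree(8, birth_rate=1.0, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_tree):
    """A compact simulated dataset with implanted accelerations."""
    config = SimulationConfig(
        seed=7, n_taxa=8, n_genes=120, outlier_fraction=0.05,
        acceleration=5.0, noise_sigma=0.1, missingness=0.05,
    )
    tensors, truth = simulate_tensor(small_tree, config)
    return tensors, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_tensor(rng, n_genes=20, n_taxa=5, missing_frac=0.0) -> DistanceTensor:
    """A symmetric nonnegative tensor with optional symmetric missingness."""
    n = n_taxa
    values = np.zeros((n_genes, n, n))
    iu = np.triu_indices(n, k=1)
    for g in range(n_genes):
        off = rng.uniform(0.01, 1.0, size=len(iu[0]))
        if missing_frac:
            mask = rng.random(len(off)) < missing_frac
            off[mask] = np.nan
        values[g][iu] = off
        values[g][iu[1], iu[0]] = off
    gene_ids = tuple(f"g{k:03d}" for k in range(n_genes))
    taxa = tuple(f"t{k}" for k in range(n))
    return DistanceTensor("omega", taxa, gene_ids, values)
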