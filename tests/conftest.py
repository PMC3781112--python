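import numpy as np
import pytest

from aflpop.io import BinaryMarkerMatrix
from aflpop.simulate import FlockConfig, simulate_flock


@pytest.fixture(scope="session")
def three_species_flock():
    """Well-separated 3-species flock for clustering/tree tests."""
    cfg = FlockConfig(
        n_species=3,
        species_names=("A", "B", "C"),
        n_per_species=(12, 12, 12),
        n_loci=300,
        frac_outlier=0.0,
        fst_neutral=0.25,
        fst_outlier=0.5,
        introgressed_spec=None,
        expansion_params=[(1.0, 0.0, 3.0)] * 3,
        seed=10,
    )
    return simulate_flock(cfg)


@pytest.fixture(scope="session")
def neutral_flock():
    """Six-species neutral flock at study-like size (no outliers)."""
    cfg = FlockConfig(
        n_loci=2000,
        frac_outlier=0.0,
        fst_neutral=0.10,
        fst_outlier=0.5,
        introgressed_spec=None,
        seed=42,
    )
    return simulate_flock(cfg)


@pytest.fixture
def tiny_matrix():
    data = np.array(
        [
            [1, 1, 0, 0, 1],
            [1, 0, 0, 1, 1],
            [0, 1, 1, 0, 0],
            [0, 1, 1, 1, 0],
        ]
    )
    return BinaryMarkerMatrix(
        data=data,
        sample_ids=["a1", "a2", "b1", "b2"],
        locus_ids=[f"L{j}" for j in range(5)],
        species=["A", "A", "B", "B"],
    )
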