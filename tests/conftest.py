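import numpy as np
import pytest

from rexome.core import Pedigree, TargetRegions
from rexome.simulate import SimulationParams, simulate_dataset


@pytest.fixture
def tiny_targets() -> TargetRegions:
    """Three intervals on two chromosomes, 30 bases total."""
    return TargetRegions(
        [("chr1", 0, 10), ("chr1", 20, 30), ("chr2", 5, 15)]
    )


@pytest.fixture
def family_pedigree() -> Pedigree:
    """Six members over three generations (three trios)."""
    return Pedigree(
        [
            ("GF01", None, None, 1),
            ("GM01", None, None, 2),
            ("MO01", "GF01", "GM01", 2),
            ("FA01", None, None, 1),
            ("CH01", "FA01", "MO01", 1),
            ("CH02", "FA01", "MO01", 2),
        ]
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully structured synthetic study (shared across tests)."""
    params = SimulationParams(seed=7, n_targets=120, target_length_mean=150)
    return simulate_dataset(params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
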