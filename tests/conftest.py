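import numpy as np
import pytest

import strokeconn as sc


@pytest.fixture(scope="session")
def smn_set() -> sc.RoiSet:
    return sc.smn()


@pytest.fixture(scope="session")
def small_cohort():
    """A small null cohort shared by cheap integration tests."""
    cfg = sc.SimulationConfig(
        n_subjects=12, n_rois=24, n_timepoints=120, noise_sd=1.0, seed=42
    )
    return sc.simulate_cohort(cfg)


def random_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Symmetric binary adjacency matrix with zero diagonal."""
    A = (rng.random((n, n)) < p).astype(int)
    A = np.triu(A, 1)
    return A + A.T
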