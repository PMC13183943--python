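import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import climkit as ck
from climkit.synthetic import SimulationSpec, random_fitness_map, simulate_library

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return ck.default_design()


@pytest.fixture(scope="session")
def fitness_map(design):
    return random_fitness_map(design, seed=7)


@pytest.fixture(scope="session")
def clean_library(design, fitness_map, tmp_path_factory):
    """Small error-free simulated screen shared across tests."""
    spec = SimulationSpec(
        true_relative_fitness=fitness_map,
        depth_t0=20_000,
        depth_t1=20_000,
        per_base_error=0.0,
        seed=11,
    )
    out = tmp_path_factory.mktemp("clean_library")
    return simulate_library(design, spec, out)


def exact_linear_coords(n_train: int, n_val: int, p: int, seed: int = 0):
    """Coordinates whose *training block* is centered and orthonormal,
    so a covariance mode fit on it recovers a planted linear relation
    exactly (training sample correlations between coordinates vanish)."""
    rng = np.random.default_rng(seed)
    A = rng.normal(0, 1, (n_train, p))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    X = np.vstack([Q, rng.normal(0, 1, (n_val, p))])
    train_mask = np.arange(n_train + n_val) < n_train
    return X, train_mask


def make_pair(insert: str, read_len: int = 150, q: int = 40):
    """Sequencer-orientation read pair covering an insert end to end."""
    from climkit.read_processing import revcomp

    r1 = insert[:read_len]
    r2 = revcomp(insert[len(insert) - read_len :])
    qual = np.full(read_len, q, dtype=np.int16)
    return (r1, qual.copy()), (r2, qual.copy())
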