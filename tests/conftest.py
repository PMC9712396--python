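import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ocsnet.connectome import ConnectivityMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_connectivity(seed: int, n: int = 8, scale: float = 0.9) -> ConnectivityMatrix:
    """Dense random weighted graph with weights in (0, scale]."""
    rng = np.random.default_rng(seed)
    w = rng.random((n, n)) * scale
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    return ConnectivityMatrix(w, tuple(f"n{i}" for i in range(n)))


def planted_block_matrix(
    seed: int,
    n: int = 30,
    k: int = 3,
    within: float = 0.8,
    between: float = 0.1,
    jitter: float = 0.02,
) -> tuple[ConnectivityMatrix, np.ndarray]:
    """Block-structured matrix with noisy within/between weights + labels."""
    rng = np.random.default_rng(seed)
    memb = np.arange(n) * k // n
    w = np.where(memb[:, None] == memb[None, :], within, between).astype(float)
    w += rng.uniform(-jitter, jitter, (n, n))
    w = np.clip((w + w.T) / 2, 0, 1)
    np.fill_diagonal(w, 0)
    return ConnectivityMatrix(w, tuple(f"n{i}" for i in range(n))), memb


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
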