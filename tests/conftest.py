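import numpy as np
import pytest

from tdgbh import PValueMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240519)


@pytest.fixture
def uniform_matrix(rng):
    """A 60 x 8 matrix of i.i.d. uniform p-values (pure null)."""
    return PValueMatrix(rng.uniform(size=(60, 8)))


@pytest.fixture
def signal_matrix(rng):
    """A 60 x 8 matrix with a signal-rich top-left block."""
    p = rng.uniform(size=(60, 8))
    p[:10, :3] = rng.uniform(high=1e-4, size=(10, 3))
    return PValueMatrix(p)


def brute_force_bh_rejections(p: np.ndarray, alpha: float) -> np.ndarray:
    """Independent step-up oracle: reject the largest k hypotheses with
    sorted p_(k) <= k * alpha / M."""
    flat = np.asarray(p, dtype=float).ravel()
    M = flat.size
    order = np.argsort(flat, kind="stable")
    ps = flat[order]
    ks = np.flatnonzero(ps <= (np.arange(1, M + 1) * alpha / M))
    rejected = np.zeros(M, dtype=bool)
    if ks.size:
        rejected[order[: ks[-1] + 1]] = True
    return rejected.reshape(np.asarray(p).shape)
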