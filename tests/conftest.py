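import numpy as np
import pytest


def random_spd(rng: np.random.Generator, n: int, scale: float = 1.0) -> np.ndarray:
    """Well-conditioned random SPD matrix (Wishart plus a ridge)."""
    A = rng.standard_normal((n, n))
    C = A @ A.T / n + 0.2 * np.eye(n)
    return scale * C


def random_spd_stack(rng: np.random.Generator, count: int, n: int) -> np.ndarray:
    return np.stack([random_spd(rng, n) for _ in range(count)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_synthetic():
    """Modest synthetic recording shared by detection/evaluation tests:
    8 channels, 128 Hz, 5 minutes, default three-regime structure."""
    from rpotatoes.simulate import default_sleep_spec, generate

    spec = default_sleep_spec(n_channels=8, fs=128.0, duration_s=300.0, seed=7)
    return generate(spec)
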