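import numpy as np
import pytest

from sleepcortex import ModelParameters, resolve_preset


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def n2() -> ModelParameters:
    return resolve_preset("n2")


@pytest.fixture(scope="session")
def n3() -> ModelParameters:
    return resolve_preset("n3")


@pytest.fixture(scope="session")
def wake() -> ModelParameters:
    return resolve_preset("wake")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def planted_kc_trace(fs: float = 200.0, duration_s: float = 30.0,
                     times_s=(6.0, 14.0, 23.0), depth: float = -5.0,
                     seed: int = 7):
    """Synthetic z-scale trace: Gaussian background with inserted
    K-complex templates (half-cosine trough followed by a rebound)."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    x = rng.standard_normal(n) * 0.3
    t_trough = []
    for t0 in times_s:
        i0 = int(t0 * fs)
        n_down = int(0.5 * fs)
        n_up = int(0.4 * fs)
        down = depth * np.sin(np.linspace(0, np.pi, n_down))
        up = 2.5 * np.sin(np.linspace(0, np.pi, n_up))
        x[i0:i0 + n_down] += down
        x[i0 + n_down:i0 + n_down + n_up] += up
        t_trough.append((i0 + n_down / 2.0) / fs)
    return x, np.array(t_trough), fs
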