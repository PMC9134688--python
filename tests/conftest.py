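import numpy as np
import pytest

from myelinquant import make_scheme
from myelinquant.synthetic import default_phantom_spec


@pytest.fixture(scope="session")
def scheme31():
    """The study acquisition: 30 directions at b = 970 plus one b = 0."""
    return make_scheme(30, 970.0, 1, seed=0)


@pytest.fixture(scope="session")
def noiseless_study(scheme31):
    """Tiny noiseless two-group phantom study shared across tests."""
    from myelinquant.synthetic import simulate_dwi

    spec = default_phantom_spec(
        n_per_group=1, snr=np.inf, seed=11, grid_shape=(8, 8, 6)
    )
    volumes, truth = simulate_dwi(spec, scheme31)
    return spec, volumes, truth


def random_spd_tensors(n: int, seed: int) -> np.ndarray:
    """Random symmetric positive-definite tensors at diffusivity scale."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, 3, 3))
    spd = A @ np.swapaxes(A, -1, -2) + 0.05 * np.eye(3)
    return spd * 3e-4
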