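import numpy as np
import pytest

from prostreg.phantom import PhantomSpec, make_phantom_pair


@pytest.fixture(scope="session")
def small_spec():
    """16^3 phantom spec used by fast unit tests."""
    return PhantomSpec(
        grid_shape=(16, 16, 16),
        organ_semiaxes_vox=(5.0, 6.0, 5.0),
        deform_amplitude_vox=2.0,
        deform_smoothness_vox=4.0,
        n_landmarks=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_case(small_spec):
    return make_phantom_pair(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def numeric_grad(f, x, eps=1e-5):
    """Central-difference gradient of scalar-valued f at x (elementwise)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g
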