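import numpy as np
import pytest

from octseg.phantom import PhantomParams, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_phantom():
    """64x64 phantom frame with a centered 6-px lumen."""
    params = PhantomParams(image_size=64, lumen_radius=6, wall_thickness=6)
    image, mask = generate_phantom(params, seed=7)
    return image, mask, params


@pytest.fixture
def float64_grad(monkeypatch):
    """Run the autodiff engine in float64 for finite-difference checks."""
    import octseg.grad.functional as fmod
    import octseg.grad.modules as mmod
    import octseg.grad.tensor as tmod

    for mod in (tmod, fmod, mmod):
        monkeypatch.setattr(mod, "DTYPE", np.float64)
    yield


def numeric_gradient(f, x, eps=1e-6):
    """Central-difference gradient of scalar-valued f w.r.t. Tensor x."""
    g = np.zeros_like(x.data)
    it = np.nditer(x.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x.data[i]
        x.data[i] = orig + eps
        hi = f().item()
        x.data[i] = orig - eps
        lo = f().item()
        x.data[i] = orig
        g[i] = (hi - lo) / (2 * eps)
    return g
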