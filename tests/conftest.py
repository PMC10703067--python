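import numpy as np
import pytest

from tunet.autodiff import Tensor
from tunet.network import ModelConfig
from tunet.synthetic import PhantomSpec, generate_phantom


def numeric_grad(fn, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient of scalar fn at x (float64)."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(x)
        flat[i] = orig - eps
        lo = fn(x)
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g


def analytic_grad(fn, x: np.ndarray) -> np.ndarray:
    """Backward-pass gradient of scalar Tensor-valued fn at x (float64)."""
    t = Tensor(np.asarray(x, dtype=np.float64), requires_grad=True)
    out = fn(t)
    out.backward()
    return t.grad


def check_grad(fn, x, atol=1e-4, rtol=1e-4):
    """Assert backward gradients match central differences."""
    num = numeric_grad(lambda a: fn(Tensor(np.asarray(a, dtype=np.float64))).item(), x)
    ana = analytic_grad(fn, x)
    np.testing.assert_allclose(ana, num, atol=atol, rtol=rtol)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def micro_config(**overrides) -> ModelConfig:
    """Smallest usable architecture for shape/structure tests."""
    base = dict(base_channels=(4, 8, 12, 16, 20), embed_dim=16, num_layers=1,
                num_heads=2, mlp_dim=32, pool_fields=(1, 2, 2, 4),
                image_size=64)
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture
def phantom_spec():
    return PhantomSpec(image_size=64, target_kind="blob", seed=11)


@pytest.fixture
def phantom_batch(phantom_spec):
    return [generate_phantom(phantom_spec, i) for i in range(4)]


def random_mask(rng, shape, p=0.4):
    m = (rng.uniform(size=shape) < p).astype(np.uint8)
    return m
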