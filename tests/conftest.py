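import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def gradcheck(func, tensors, eps=1e-6, rtol=1e-4, atol=1e-6):
    """Central-difference gradient check in float64.

    ``func`` maps the tensors to a scalar Tensor; every tensor in ``tensors``
    must hold float64 data with requires_grad=True.
    """
    out = func(*tensors)
    out.backward()
    for t in tensors:
        analytic = t.grad.copy()
        numeric = np.zeros_like(t.data)
        flat = t.data.reshape(-1)
        num_flat = numeric.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = func(*tensors).item()
            flat[i] = orig - eps
            lo = func(*tensors).item()
            flat[i] = orig
            num_flat[i] = (hi - lo) / (2 * eps)
        np.testing.assert_allclose(analytic, numeric, rtol=rtol, atol=atol)
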