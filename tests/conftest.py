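import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def numeric_grad(f, x, eps=1e-5):
    """Central-difference gradient of scalar f at float64 array x."""
    g = np.zeros_like(x)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        old = flat[i]
        flat[i] = old + eps
        fp = f()
        flat[i] = old - eps
        fm = f()
        flat[i] = old
        gf[i] = (fp - fm) / (2 * eps)
    return g
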