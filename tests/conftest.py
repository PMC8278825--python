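import numpy as np
import pytest

from picslim.types import FieldDecomposition


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_decomp(shape=(16, 16), a=1.0, b=0.5, delta_phi=0.0):
    """Uniform-field decomposition helper."""
    return FieldDecomposition(
        a_incident=np.full(shape, a),
        b_scattered=np.full(shape, b),
        delta_phi=np.full(shape, delta_phi),
    )


def random_decomp(rng, shape=(16, 16), b=0.3):
    """Random phase field with uniform amplitudes."""
    return FieldDecomposition(
        a_incident=np.ones(shape),
        b_scattered=np.full(shape, b),
        delta_phi=rng.uniform(-np.pi, np.pi, shape),
    )
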