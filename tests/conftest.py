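import numpy as np
import pytest

from pcwave.params import GainPair, Hyperparams


@pytest.fixture
def identity_gains():
    return GainPair.identity()


@pytest.fixture
def generic_params():
    """A marginally stable parameter point with beta > 0 and c0 > 0."""
    return Hyperparams(0.4, 0.3, 0.3)


def dirac(size: int = 1, at: int = 0) -> np.ndarray:
    h = np.zeros(size)
    h[at] = 1.0
    return h
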