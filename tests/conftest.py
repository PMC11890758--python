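import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def x_grid():
    """Default acceptor/donor titration grid."""
    return np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0])
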