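import numpy as np
import pytest

from promchip import FragmentLengthDist, peak_shape


@pytest.fixture(scope="session")
def uniform_shape():
    """Binding-event profile for the default 200-700 bp fragment range."""
    return peak_shape(FragmentLengthDist.uniform())


@pytest.fixture()
def jittered_offsets():
    """A 5-probe promoter with irregular (non-mirror-symmetric) spacing."""
    return np.array([-1480.0, -1170.0, -920.0, -590.0, -330.0])
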