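import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from qvoter.model_core import ModelParams


@pytest.fixture
def small_params():
    return ModelParams(q=3, r=2, w=2, p=0.3, z=0.5, N=50)


@pytest.fixture
def noise_params():
    """Pure independence: the chain reduces to an Ehrenfest-type urn."""
    return ModelParams(q=3, r=2, w=2, p=1.0, z=1.0, N=20)
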