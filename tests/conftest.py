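import numpy as np
import pytest
from hypothesis import settings

import helixfit as hf

settings.register_profile("ci", derandomize=True, max_examples=200, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth_long() -> hf.ModelParameters:
    """Ground truth of the cooperative long-chain fixture."""
    return hf.default_truth("cd_long")


@pytest.fixture(scope="session")
def cd_grid() -> np.ndarray:
    lo, hi = hf.synthetic.FIXTURE_CD_GRID
    return np.linspace(lo, hi, 200)


@pytest.fixture(scope="session")
def transition_grid(truth_long) -> np.ndarray:
    """Temperatures spanning the heat-denaturation transition of the fixture."""
    return np.linspace(335.0, 420.0, 200)
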