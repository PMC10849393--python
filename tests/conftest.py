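import numpy as np
import pytest

from matchcontrol import SpineParams, SpikeTrain, build_geometry


@pytest.fixture(scope="session")
def params():
    """Default spine-model parameters."""
    return SpineParams()


@pytest.fixture(scope="session")
def quiet_params():
    """Noiseless spine-model parameters for deterministic checks."""
    from dataclasses import replace

    return replace(SpineParams(), noise_sd=0.0)


@pytest.fixture(scope="session")
def geometry():
    return build_geometry(150, 10)


@pytest.fixture
def toy_train():
    return SpikeTrain(np.array([0.1, 0.3, 0.65]), 1.0, label="toy")
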