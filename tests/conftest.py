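import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vnokit.protocol import Application, StimulusProtocol, two_stimulus_protocol

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def protocol():
    """Default alternating two-stimulus protocol (A, B, A, B)."""
    return two_stimulus_protocol()


@pytest.fixture
def short_protocol():
    """Compact single-stimulus protocol (two applications) for fast tests.

    Onsets 102 frames apart violate the 4-min inter-stimulus advisory, which
    only warns; detection behaviour is unchanged.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return StimulusProtocol(
            applications=[Application("A", 60), Application("A", 102)]
        )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
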