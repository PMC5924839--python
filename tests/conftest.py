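import numpy as np
import pytest

from sdhspike import (GridSpec, NeuronParameters, StimulusProtocol, build_map)

#: the five canonical (g_K,lt, g_K,A) settings and their expected patterns
CANONICAL_SETTINGS = [
    ((0.0, 0.0), "TONIC"),
    ((6.0, 0.0), "SINGLE"),
    ((0.0, 8.0), "DELAYED"),
    ((0.0, 5.0), "GAP"),
    ((6.0, 8.0), "RELUCTANT"),
]


@pytest.fixture(scope="session")
def protocol60() -> StimulusProtocol:
    return StimulusProtocol(I_stim=60.0)


@pytest.fixture(scope="session")
def coarse_map(protocol60):
    """Pattern map on a 0.5 mS/cm^2 grid; cheap stand-in for unit tests."""
    return build_map(GridSpec(step=0.5), protocol60, NeuronParameters())


@pytest.fixture(scope="session")
def full_map(protocol60):
    """The reference map: 0-20 mS/cm^2 at 0.1 mS/cm^2, I_stim = 60 uA/cm^2."""
    return build_map(GridSpec(), protocol60, NeuronParameters())
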