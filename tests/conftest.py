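import numpy as np
import pytest

from teng_neuron import (
    AxonConfig,
    MembraneParams,
    MicropatternSpec,
    StimulusProtocol,
    TENGConfig,
    build_curve,
    default_gap_grid,
)


@pytest.fixture(scope="session")
def teng_cfg() -> TENGConfig:
    """Device build with the standard silk/Kapton parameter set."""
    return TENGConfig()


@pytest.fixture(scope="session")
def membrane() -> MembraneParams:
    return MembraneParams()


@pytest.fixture(scope="session")
def axon() -> AxonConfig:
    return AxonConfig()


@pytest.fixture(scope="session")
def short_axon() -> AxonConfig:
    """Shorter horizon for single-run unit tests."""
    return AxonConfig(t_end=50.0)


@pytest.fixture(scope="session")
def flat_curve(teng_cfg):
    """Default 21-node closed-form flat-device curve."""
    return build_curve(teng_cfg, default_gap_grid(), method="closed_form")


@pytest.fixture(scope="session")
def firing_stim() -> StimulusProtocol:
    return StimulusProtocol(amplitude=10.0, t_on=0.0, t_off=100.0)
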