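"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from collagenmech.biphasic import BiphasicParams
from collagenmech.compression import GelGeometry, StepProtocol
from collagenmech.synthetic import gen_biphasic_trace


@pytest.fixture(scope="session")
def geometry() -> GelGeometry:
    return GelGeometry()


@pytest.fixture(scope="session")
def protocol_2step() -> StepProtocol:
    # two 3% steps with short holds keep unit tests fast while still
    # exercising segmentation and per-step logic
    return StepProtocol(step_strain=0.03, ramp_rate=0.01, hold_duration=120.0, n_steps=2)


@pytest.fixture(scope="session")
def true_params() -> BiphasicParams:
    return BiphasicParams(c1=250.0, c2=-50.0, c3=1000.0, k=1e-10)


@pytest.fixture(scope="session")
def clean_trace(true_params, protocol_2step, geometry):
    """Noiseless synthetic two-step confined-compression trace."""
    return gen_biphasic_trace(true_params, protocol_2step, geometry, seed=0)
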