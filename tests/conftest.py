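import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from bvocmc import (
    Environment,
    SourceEvent,
    ReceiverSphere,
    QuadratureSpec,
    DispersionScheme,
    FieldOptions,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def env():
    """Reference environment (Table-defaults, u = 3 m/s)."""
    return Environment()


@pytest.fixture(scope="session")
def env295():
    return Environment(T=295.0)


@pytest.fixture(scope="session")
def src():
    return SourceEvent(m=0.0016, H=0.8)


@pytest.fixture(scope="session")
def rx():
    return ReceiverSphere(center=(1.0, 0.0, 0.6), radius=0.15, tau=2.0)


@pytest.fixture(scope="session")
def quad_fast():
    """Coarser-but-converged quadrature for sweep-heavy tests."""
    return QuadratureSpec(spatial_resolution=(8, 8))


@pytest.fixture(scope="session")
def no_loss_opts():
    return FieldOptions(include_drift=False, include_decay=False)
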