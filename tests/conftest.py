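"""Shared fixtures: expensive simulations run once per session."""

import numpy as np
import pytest

from suctionsim import (default_config, full_protocol, hypovolemia_ramp,
                        run_steady)
from suctionsim.validation import generate_report


@pytest.fixture(scope="session")
def dcm_config():
    return default_config("DCM")


@pytest.fixture(scope="session")
def rcm_config():
    return default_config("RCM")


@pytest.fixture(scope="session")
def dcm_steady(dcm_config):
    """Settled DCM baseline at 2,800 rpm: (record, summary)."""
    return run_steady(dcm_config, duration=20.0)


@pytest.fixture(scope="session")
def rcm_steady(rcm_config):
    return run_steady(rcm_config, duration=20.0)


@pytest.fixture(scope="session")
def dcm_ramp(dcm_config):
    """One hypovolemia ramp (DCM at 2,800 rpm): list of stage records."""
    return hypovolemia_ramp(dcm_config, 2800.0)


@pytest.fixture(scope="session")
def protocol_dataset(dcm_config):
    """Full two-profile, three-speed protocol beat dataset."""
    return full_protocol(dcm_config)


@pytest.fixture(scope="session")
def protocol_report(protocol_dataset):
    """Validation report with the shipped (calibrated) tree thresholds."""
    return generate_report(protocol_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
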