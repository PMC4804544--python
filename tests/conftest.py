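"""Shared fixtures: reference parameterisation and cached long-horizon runs."""

import numpy as np
import pytest

from angiosim import (
    GrowthParams,
    PkParams,
    TumourState,
    make_regimen,
    simulate,
)

#: Nine twice-weekly 5 mg/kg administrations to a 25 g host.
NINE_DOSE_DAYS = (1.0, 4.0, 8.0, 11.0, 15.0, 18.0, 22.0, 25.0, 29.0)


@pytest.fixture(scope="session")
def ref_params():
    """Reference mouse growth parameters (lambda1=0.192, c=5.85, d=0.00873)."""
    return GrowthParams()


@pytest.fixture(scope="session")
def pk_params():
    """Reference mouse PK micro-constants."""
    return PkParams()


@pytest.fixture(scope="session")
def regimen_9x5():
    return make_regimen(5.0, weight=0.025, days=NINE_DOSE_DAYS, duration=1.0 / 48.0)


@pytest.fixture(scope="session")
def init_state():
    """Vascularised starting state shared by the indicative scenarios."""
    return TumourState(V=200.0, K=625.0)


@pytest.fixture(scope="session")
def free_trajectory(ref_params, init_state):
    """Reference free-growth run, long enough to plateau."""
    return simulate(ref_params, init_state, (0.0, 300.0))


@pytest.fixture(scope="session")
def treated_trajectory(ref_params, init_state, regimen_9x5, pk_params):
    """Reference nine-dose treated run, long enough to wash out and re-plateau."""
    return simulate(
        ref_params, init_state, (0.0, 300.0), regimen=regimen_9x5, pk=pk_params
    )
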