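import numpy as np
import pytest

from glykit.defaults import healthy_reference_parameters
from glykit.model import simulate_sampled_fast
from glykit.records import OGTTRecord

OGTT_TIMES = (0.0, 30.0, 60.0, 90.0, 120.0)


@pytest.fixture(scope="session")
def healthy_params():
    """Population-centre parameter vector of the healthy template."""
    return healthy_reference_parameters()


@pytest.fixture(scope="session")
def noiseless_record(healthy_params):
    """Exact model output at the 5 protocol times, no measurement noise."""
    G, I = simulate_sampled_fast(healthy_params, np.asarray(OGTT_TIMES))
    return OGTTRecord(
        subject_id="centre",
        times=OGTT_TIMES,
        glycemia=tuple(G),
        insulinemia=tuple(I),
    )


@pytest.fixture(scope="session")
def centre_fit(noiseless_record):
    """One multi-start fit of the noiseless centre record, shared by tests."""
    from glykit.fitting import GlucoseInsulinModel

    return GlucoseInsulinModel(noiseless_record, dt=1.0).fit(seed=1, n_starts=8)
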