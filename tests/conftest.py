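import numpy as np
import pytest

from rubikit.assay import AssayConstants
from rubikit.synthetic import TruthRecord, simulate_titration_series


@pytest.fixture
def constants():
    return AssayConstants()


@pytest.fixture
def worked_series(constants):
    """Noiseless ladder from the worked truth: 50 nM sites, kcat 0.2 s^-1.

    Expected fluxes on the default ladder: (0,10),(0,10),(10,8),(20,6),
    (30,4),(90,0) nM/s.
    """
    truth = TruthRecord("worked", kcat_true=0.2, site_conc_true_nM=50.0)
    return simulate_titration_series(truth, constants, seed=7)


def ols_slope_2pt(times, y):
    """Closed-form slope from the two endpoints of an exactly linear trace."""
    return (y[-1] - y[0]) / (times[-1] - times[0])
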