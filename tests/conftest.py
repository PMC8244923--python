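import numpy as np
import pytest

import trisyn as ts


@pytest.fixture(scope="session")
def model_small_ecs():
    """Calibrated model at the realistic (20%) extracellular volume fraction."""
    return ts.calibrate(alpha_e=0.2)


@pytest.fixture(scope="session")
def model_large_ecs():
    """Calibrated model at the large (80%) extracellular volume fraction."""
    return ts.calibrate(alpha_e=0.8)


@pytest.fixture(scope="session")
def baseline_view(model_small_ecs):
    m = model_small_ecs
    return ts.compartment_view(m.y0, m.totals, m.geom, m.consts)


@pytest.fixture(scope="session")
def consts():
    return ts.PhysicalConstants()
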