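import numpy as np
import pytest

from hemoswarm.fitness import OperatingPointRecord
from hemoswarm.hemomodels import get_constant_set
from hemoswarm.stressfield import StressField


@pytest.fixture
def gw():
    return get_constant_set("GW")


@pytest.fixture
def ho():
    return get_constant_set("HO")


@pytest.fixture
def uniform_field():
    """Single-cell field: tau=100 Pa, V=1e-6 m^3, Q=1e-6 m^3/s (t_res=1 s)."""
    return StressField(
        cell_volumes=np.array([1e-6]),
        tau_eff=np.array([100.0]),
        Q=1e-6,
        label="uniform",
    )


def uniform_op_record(label, tau, t_res, mih_exp, band_fraction):
    """Uniform-stress operating point backed by a one-cell field."""
    Q = 1e-5
    f = StressField(np.array([t_res * Q]), np.array([tau]), Q, label)
    return OperatingPointRecord(
        label=label,
        mih_exp=mih_exp,
        mih_unc=band_fraction * mih_exp,
        field=f,
        group="uniform",
    )
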