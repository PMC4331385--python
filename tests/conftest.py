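import numpy as np
import pytest

from cmrperf.curves import ConcentrationCurve
from cmrperf.kinetics import DPParams
from cmrperf.signal import AcquisitionParams, Calibration


@pytest.fixture
def acq() -> AcquisitionParams:
    """Protocol-typical acquisition constants."""
    return AcquisitionParams()


@pytest.fixture
def cal() -> Calibration:
    return Calibration(psi=1000.0, native_t1=1.2)


@pytest.fixture
def dp_params() -> DPParams:
    """Physiological stress-range distributed-parameter ground truth."""
    return DPParams(mbf=3.0, t_overall=12.0, t_cap=3.0, t_int=14.0)


@pytest.fixture
def gaussian_aif() -> ConcentrationCurve:
    """Smooth single-peak arterial curve on a 1 s grid (no recirculation)."""
    t = np.arange(64, dtype=float)
    values = 4.0 * np.exp(-0.5 * ((t - 15.0) / 4.0) ** 2)
    return ConcentrationCurve(times=t, values=values, region_label="AIF")
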