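import numpy as np
import pytest

from guancest import synthetic_data as sd


@pytest.fixture(scope="session")
def acq():
    return sd.AcquisitionConfig()


@pytest.fixture(scope="session")
def acq_noise_free():
    return sd.AcquisitionConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def offsets(acq):
    return np.asarray(acq.offsets_ppm)


@pytest.fixture(scope="session")
def small_cohort():
    return sd.simulate_clinical_cohort(4, 4, seed=123)
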