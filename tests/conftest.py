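import numpy as np
import pytest

from mixtoxsys.doseresponse import DoseResponseModel
from mixtoxsys.mixture_models import SurfaceParams


@pytest.fixture
def simple_model():
    return DoseResponseModel(theta_max=100.0, ec50=1.0, beta=2.0)


@pytest.fixture
def lms_like_surface():
    """A CA/IA reference surface with marginals resembling the LMS endpoint."""
    return SurfaceParams(
        theta_max=100.0, ec50_1=0.77, beta_1=2.0, ec50_2=4.5, beta_2=1.5
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
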