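import logging

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from inrf.core import INRFParams
from inrf.primitives import KernelSpec, NonlinearitySpec

# the even-extent rounding warning is expected noise in tests
logging.getLogger("inrf").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_inrf_params():
    """A small INRF instance usable at desk scale (kernels a few px)."""
    return INRFParams(
        m=KernelSpec(kind="gaussian", sigma_px=2.0),
        w=KernelSpec(kind="gaussian", sigma_px=5.0),
        g=KernelSpec(kind="delta"),
        lambda_weight=2.0,
        sigma=NonlinearitySpec(kind="asymmetric_power", p=0.625, q=0.775),
    )
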