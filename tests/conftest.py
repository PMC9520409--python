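import numpy as np
import pytest

from avnode.av_network import ModelParams, PathwayParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def reference_params():
    """Mid-range pathway parameters (ensemble means of the fitted sets)."""
    sp = PathwayParams(r_min=339, delta_r=232, tau_r=160,
                       d_min=20, delta_d=39, tau_d=171)
    fp = PathwayParams(r_min=493, delta_r=369, tau_r=162,
                       d_min=7, delta_d=23, tau_d=163)
    return ModelParams(sp=sp, fp=fp)
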