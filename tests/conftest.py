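import pytest

from fermscale import build_design_matrix, case_study
from fermscale.replicate import DESIGN_SPEEDS


@pytest.fixture(scope="session")
def fx():
    """The bundled three-scale case study."""
    return case_study()


@pytest.fixture(scope="session")
def industrial_matrix(fx):
    """Industrial design matrix over the standard speed grid, 2/3 stages."""
    return build_design_matrix(fx.industrial, DESIGN_SPEEDS, (2, 3))
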