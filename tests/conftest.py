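import numpy as np
import pytest

from photokv.tension import TensionParams


@pytest.fixture
def printed_params() -> TensionParams:
    """The worked geometry/mechanics of the torus-relaxation estimate:
    r0 = 29.5 um, r_in = 27.5 um, sigma0 = 4 mN/m, tau = 23 ms, and the
    upper-bound surface viscosity 500 nN*s/m."""
    return TensionParams(
        r0_um=29.5, rin_um=27.5, sigma0_mN_per_m=4.0,
        eta_h_nNs_per_m=500.0, tau_ms=23.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
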