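import numpy as np
import pytest
from scipy.special import erf, erfinv

from beamdeconv import Profile, ProfileMeta


def erf_field(lam, width=60.0, halfspan=80.0, step=1.0, tail=0.0):
    """Two-edge error-function field profile on a uniform grid, CAX = 1.

    For edge softness ``lam`` small against the field width the 20-80%
    penumbra width of each edge is analytically 2*sqrt(2)*erfinv(0.6)*lam.
    """
    n = int(round(halfspan / step))
    x = np.arange(-n, n + 1) * step
    s = np.sqrt(2.0) * lam
    base = 0.5 * (erf((width / 2.0 - x) / s) + erf((width / 2.0 + x) / s))
    vals = base + tail * (1.0 - base)
    return Profile(x, vals / vals[n], ProfileMeta(role="true"))


def analytic_penumbra_width(lam):
    """20-80% width of an isolated erf edge with softness lam (mm)."""
    return float(2.0 * np.sqrt(2.0) * erfinv(0.6) * lam)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
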