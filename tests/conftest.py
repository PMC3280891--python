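import numpy as np
import pytest

from cochlea.filters import FilterParameters
from cochlea.tonotopy import ScaleGrid, TonotopicMap
from cochlea.transform import SampledSignal, analytic_transform


@pytest.fixture(scope="session")
def tmap_hz():
    return TonotopicMap(units="hz")


@pytest.fixture(scope="session")
def tmap_rad(tmap_hz):
    return tmap_hz.in_units("rad/s")


@pytest.fixture(scope="session")
def p1():
    return FilterParameters(c=1.0)


def make_tone_setup(c=1.0, rate=8192.0, n=8192, f_hz=64.0, n_scales=48,
                    span=(0.45, 2.2), amplitude=1.0, phase=0.0,
                    include_on_cf=False):
    """Exact-bin tone + log-spaced grid around its scale; pad=False keeps
    the circular filtering exact.  With ``include_on_cf`` the grid is
    shifted so that a*nu = 1 is hit exactly by one row."""
    t = np.arange(n) / rate
    nu = 2 * np.pi * f_hz
    sig = SampledSignal(amplitude * np.cos(nu * t + phase), rate)
    p = FilterParameters(c=c)
    scales = np.geomspace(span[0] / nu, span[1] / nu, n_scales)
    if include_on_cf:
        j0 = int(np.argmin(np.abs(scales * nu - 1.0)))
        scales = scales / (nu * scales[j0])
    grid = ScaleGrid(scales=scales, k_const=0.0)
    coch = analytic_transform(sig, grid, p, pad=False)
    return {"t": t, "nu": nu, "sig": sig, "p": p, "grid": grid, "coch": coch,
            "rate": rate, "n": n}


@pytest.fixture(scope="session")
def tone_c1():
    return make_tone_setup(c=1.0)


@pytest.fixture(scope="session")
def tone_c2():
    return make_tone_setup(c=2.0)
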