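import numpy as np
import pytest

from radiosynergy.combination import FixedRatioDesign, combination_index
from radiosynergy.dose_response import DoseResponseCurve, fit_median_effect


def four_pl(d, ec50, hill=1.0, top=1.0, bottom=0.0):
    d = np.asarray(d, float)
    return bottom + (top - bottom) / (1.0 + (d / ec50) ** hill)


def sham_ci(hill: float, ec50: float = 10.0, top: float = 50.0):
    """Self-combination sham: the same drug on both axes with equal tops.

    A mixture at fraction f of the tops physically contains total dose
    f·top of the one drug, so every mixture curve equals the single-agent
    curve and the true CI is exactly 1 at every ratio.
    """
    d_grid = np.geomspace(0.01, top, 9)
    f_grid = np.geomspace(1e-3, 1.0, 9)
    single = DoseResponseCurve("A", d_grid, four_pl(d_grid, ec50, hill))
    me = fit_median_effect(single)
    mixes = [
        DoseResponseCurve("mix", f_grid, four_pl(f_grid * top, ec50, hill), unit="fraction")
        for _ in range(9)
    ]
    return combination_index(FixedRatioDesign(top, top), me, me, mixes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
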