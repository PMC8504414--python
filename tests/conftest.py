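import numpy as np
import pytest

import petrelease as pr
from petrelease.acquisition import DEFAULT_FRAMING_SCHEME, make_framing
from petrelease.kinetics import TAC


@pytest.fixture(scope="session")
def plasma():
    return pr.synthetic_plasma_input(duration_min=92.0)


@pytest.fixture(scope="session")
def framing():
    return make_framing(DEFAULT_FRAMING_SCHEME)


@pytest.fixture(scope="session")
def fine_grid():
    """1 s grid over 90 minutes."""
    return np.arange(0.0, 90.0 + 1e-9, 1.0 / 60.0)


@pytest.fixture(scope="session")
def small_phantom():
    return pr.build_phantom(shape=(32, 32, 22), voxel_size_mm=3.0, seed=1)


@pytest.fixture(scope="session")
def small_rois(small_phantom):
    return pr.generate_rois(small_phantom)


def frame_average(values, fine_times_min, framing):
    """Frame-average a 1 s-grid curve (shared test helper)."""
    t_s = fine_times_min * 60.0
    out = []
    for a, b in zip(framing.starts_s, framing.ends_s):
        sel = (t_s >= a - 1e-9) & (t_s <= b + 1e-9)
        out.append(values[sel].mean())
    return np.asarray(out)


@pytest.fixture(scope="session")
def reference_curves(plasma, framing, fine_grid):
    """Reference-region 1TC curve on the fine grid and as a frame TAC."""
    refp = pr.MicroParams(K1=0.33, k2=0.165)
    fine = pr.simulate_1tcm(refp, plasma, fine_grid).values
    tac = TAC(framing.mid_times_min, frame_average(fine, fine_grid, framing))
    return {"params": refp, "fine": fine, "tac": tac}
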