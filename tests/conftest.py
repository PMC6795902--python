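import numpy as np
import pytest

from apdmap.containers import TissueParameterMap
from apdmap.pipeline import run_scan


@pytest.fixture(scope="session")
def lqt2_scan():
    """One full small LQT2 scan through the pipeline, shared across tests."""
    return run_scan("lqt2", grid=(20, 20), seed=11, n_beats=95,
                    keep_movie=True)


def make_uniform_maps(c=150.0, alpha=(0.32, -0.053), grid=(12, 12),
                      amplitude=1.0, velocity=50.0):
    """Spatially uniform tissue maps for hand-checkable simulations."""
    h, w = grid
    return TissueParameterMap(
        c_ms=np.full(grid, float(c)),
        alpha=np.stack([np.full(grid, a) for a in alpha]),
        amplitude=np.full(grid, float(amplitude)),
        region_labels=np.zeros(grid, dtype=int),
        region_names=("base", "apex"),
        origin_px=(0, w // 2),
        conduction_velocity_cm_s=velocity,
    )


@pytest.fixture
def uniform_maps():
    return make_uniform_maps()
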