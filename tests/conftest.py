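"""Shared fixtures: reference geometries and (expensive) equilibrium shapes.

Equilibria are session-scoped because a single minimization takes tens of
seconds at production resolution; every test that needs, say, the
homogeneous-tension embryo shares one solve.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from embryoshape.ellipsoid import Ellipsoid
from embryoshape.simulator import (
    MinimizeOptions,
    TensionParams,
    minimize_shape,
)

#: reference eggshell and volumes: 25 x 15 x 15 um half-axes, cells at 95%
#: packing with AB taking 58% of the combined volume
SHELL = Ellipsoid(center=np.zeros(3), semi_axes=np.array([25.0, 15.0, 15.0]))
V_TOTAL = 0.95 * SHELL.volume
V_AB = 0.58 * V_TOTAL
V_P1 = 0.42 * V_TOTAL

#: free double bubble volumes (60:40 of two 14.7-um cubes)
V_BUBBLE = 2 * 14.7**3
V_AB_BUBBLE = 0.6 * V_BUBBLE
V_P1_BUBBLE = 0.4 * V_BUBBLE

FAST_OPTS = MinimizeOptions(
    faces_per_edge=1, max_iters=(400, 300, 250, 200), polish_iters=500
)
COARSE_OPTS = MinimizeOptions(
    faces_per_edge=1, subdivisions=2, max_iters=(300, 250, 200), polish_iters=300
)


def quiet_minimize(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return minimize_shape(*args, **kwargs)


@pytest.fixture(scope="session")
def embryo_geometry():
    return SHELL, V_AB, V_P1


@pytest.fixture(scope="session")
def homo_embryo():
    """Homogeneous-tension equilibrium in the reference eggshell (full res)."""
    return quiet_minimize(TensionParams(1.0, 1.0), V_AB, V_P1, e=SHELL)


@pytest.fixture(scope="session")
def hetero_embryo():
    """Heterogeneous-tension equilibrium (fitted tensions 3.4/3.4, full res)."""
    return quiet_minimize(TensionParams(3.4, 3.4), V_AB, V_P1, e=SHELL)


@pytest.fixture(scope="session")
def free_bubble_6040():
    """Free 60:40 double bubble at equal tensions (full res, no eggshell)."""
    return quiet_minimize(TensionParams(1.0, 1.0), V_AB_BUBBLE, V_P1_BUBBLE, e=None)


@pytest.fixture(scope="session")
def symmetric_bubble():
    """Equal-volume, equal-tension free double bubble (fast res)."""
    half = 14.7**3
    return quiet_minimize(TensionParams(1.0, 1.0), half, half, e=None, opts=FAST_OPTS)


# -- tension-recovery fixtures (shared by fitting and acceptance tests) ------

RECOVERY_GRID_KW = {"min": 3.0, "max": 3.8, "step": 0.4}
RECOVERY_TRUTH = (3.4, 3.4)


@pytest.fixture(scope="session")
def recovery_shapes():
    """Equilibria for the coarse recovery grid, keyed by (gamma_ab, gamma_cnt)."""
    from embryoshape.fitting import GridSpec, grid_equilibria, valid_tension_grid

    pairs = valid_tension_grid(GridSpec(**RECOVERY_GRID_KW))
    return grid_equilibria(pairs, V_AB, V_P1, SHELL, FAST_OPTS)


@pytest.fixture(scope="session")
def noisy_recovery_bests(recovery_shapes):
    """Best grid pair per render-noise seed (contour from render + watershed)."""
    import numpy as np
    from scipy import ndimage

    from embryoshape.fitting import GridSpec, fit_tensions
    from embryoshape.imaging import (
        LABEL_AB,
        LABEL_BOUNDARY,
        LABEL_P1,
        preprocess_stack,
        segment_stack,
    )
    from embryoshape.synth import SynthConfig, default_markers, render_stack

    truth = recovery_shapes[RECOVERY_TRUTH]
    bests = []
    for seed in (0, 1, 2):
        cfg = SynthConfig(seed=seed, spacing=(0.733, 0.733, 0.733))
        mem, _ = render_stack(truth, SHELL, cfg, noise=True)
        pre = preprocess_stack(mem)
        markers = default_markers(truth, SHELL, pre.spacing[0], margin=cfg.margin)
        seg = segment_stack(pre, markers)
        lab = seg.label_volume.labels
        cells = (lab == LABEL_AB) | (lab == LABEL_P1)
        contour = ndimage.binary_dilation(cells) & (lab == LABEL_BOUNDARY)
        pts = (np.argwhere(contour)[:, ::-1] + 0.5) * seg.label_volume.spacing
        fr = fit_tensions(pts, seg.V_AB, seg.V_P1, SHELL,
                          GridSpec(**RECOVERY_GRID_KW), shapes=recovery_shapes)
        bests.append(fr.best)
    return bests
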