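import numpy as np
import pytest

from gradchamber.diffusion import ChamberGeometry1D, DiffusionParams, solve_chamber_1d
from gradchamber.motility import Trajectory, TrackSet
from gradchamber.synth import WalkParams, simulate_tracks


@pytest.fixture(scope="session")
def params() -> DiffusionParams:
    return DiffusionParams(D_cm2_s=2e-6)


@pytest.fixture(scope="session")
def geom() -> ChamberGeometry1D:
    return ChamberGeometry1D()


@pytest.fixture(scope="session")
def chamber_field(geom, params):
    """Default finite-difference solve over the 2 h experimental window."""
    t_grid = np.arange(60.0, 7201.0, 60.0)
    return solve_chamber_1d(geom, params, t_grid)


@pytest.fixture
def three_point_trajectory() -> Trajectory:
    """The 3-4-5 worked example: (0,0) -> (0,-3) -> (4,-6)."""
    return Trajectory("c0", [0.0, 1.0, 2.0],
                      [[0, 0, 0], [0, -3, 0], [4, -6, 0]])


def straight_trajectory(direction, speed_um_min=2.0, n_frames=111,
                        cell_id="straight", diameter_um=10.0) -> Trajectory:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    t = np.arange(n_frames, dtype=float)
    return Trajectory(cell_id, t, t[:, None] * speed_um_min * d,
                      diameter_um=diameter_um)


@pytest.fixture(scope="session")
def unbiased_walk_experiment():
    """200 unbiased persistent walkers (no coupling, equal speeds)."""
    wp = WalkParams(n_cells=200, persistence=0.5, chemotactic_coupling=0.0,
                    motile_fraction_pre=1.0, motile_fraction_post=1.0,
                    speed_scale_pre_um_min=2.0, speed_scale_post_um_min=2.0,
                    seed=11)
    return simulate_tracks(wp)


@pytest.fixture
def small_trackset(three_point_trajectory) -> TrackSet:
    other = Trajectory("c1", [0.0, 1.0, 2.0],
                       [[0, 0, 0], [1, 1, 0], [0, 0, 0]], diameter_um=8.0)
    return TrackSet([three_point_trajectory, other], t_stimulus_min=1.0)
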