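import numpy as np
import pytest

from darc import fixtures as fx
from darc.scoring import RayScorer
from darc.workflow import make_rays


@pytest.fixture(scope="session")
def ligand15():
    return fx.make_ligand(15, seed=7)


@pytest.fixture(scope="session")
def selfdock(ligand15):
    """The carved-complement self-dock problem: receptor, ray map, truth.

    Built once per session; the pocket search is centered on the generating
    pose (the bound-ligand-centered benchmarking mode) and uses five origins.
    """
    receptor, true_pose, targets = fx.make_complementary_receptor(ligand15)
    raymap, grid = make_rays(receptor, targets, multiple_origins=True, seed=3,
                             near_points=true_pose,
                             near_cutoff=fx.SELFDOCK_NEAR_CUTOFF)
    return {"receptor": receptor, "true_pose": true_pose, "targets": targets,
            "raymap": raymap, "grid": grid, "ligand": ligand15,
            "scorer": RayScorer(raymap)}


@pytest.fixture(scope="session")
def ball_pocket():
    receptor, center, targets = fx.make_spherical_pocket_receptor()
    return receptor, center, targets


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
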