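import numpy as np
import pytest

import phoregen as pg
from phoregen.features import FeaturePoint, FeatureType


@pytest.fixture(scope="session")
def benzene_conf():
    return pg.embed3d(pg.parse_smiles("c1ccccc1", "benzene"), seed=1)


@pytest.fixture(scope="session")
def cyclohexane_conf():
    return pg.embed3d(pg.parse_smiles("C1CCCCC1", "cyclohexane"), seed=1)


@pytest.fixture(scope="session")
def aminothiazole_conf():
    return pg.embed3d(pg.parse_smiles("Nc1nccs1", "2-aminothiazole"), seed=2)


@pytest.fixture(scope="session")
def compound12():
    return pg.paper_compounds()[11].molecule()


def make_point(ftype, xyz, idx=0):
    return FeaturePoint(FeatureType(ftype), np.asarray(xyz, float), (idx,))


@pytest.fixture
def square_features():
    """Factory: the four rhomb corner features of a square of given side
    (HYD on opposite corners, ARO top, DON_PROJ bottom)."""

    def build(side=4.5, proj_y=None):
        h = side / np.sqrt(2.0)
        y = -h if proj_y is None else proj_y
        return [
            make_point("HYD", [h, 0, 0], 0),
            make_point("HYD", [-h, 0, 0], 1),
            make_point("ARO", [0, h, 0], 2),
            make_point("DON_PROJ", [0, y, 0], 3),
        ]

    return build


def random_rigid_motion(rng):
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-10, 10, size=3)
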