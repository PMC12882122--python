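import numpy as np
import pytest

from ringconf import fixtures


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A deterministic synthetic analysis bundle shared across tests."""
    out = tmp_path_factory.mktemp("bundle")
    resolutions = [1.5, 2.0, 2.5, 1.0, 1.8, 1.2, 1.9, 2.4, 1.07]
    manifest = fixtures.write_fixture_bundle(out, seed=7,
                                             resolutions=resolutions)
    return out, manifest


@pytest.fixture
def hexagon():
    """Regular planar hexagon with aromatic C-C bond length."""
    return fixtures.regular_polygon(6, 1.39)


def ideal_chair(amplitude=0.25, bond=1.54):
    coords = fixtures.regular_polygon(6, bond)
    coords[:, 2] = fixtures.ideal_z("cyclohexane", "chair", amplitude)
    return coords


def random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=rng).as_matrix()
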