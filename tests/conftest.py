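import numpy as np
import pytest

from cytorod import FilamentSet, Spherocylinder
from cytorod.scenarios import quat_from_director


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_rod(rng, box=2.0, length=1.0, diameter=0.025, idx=0):
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    return Spherocylinder(
        id=idx,
        center=rng.random(3) * box,
        quat=quat_from_director(u),
        length=length,
        diameter=diameter,
    )


@pytest.fixture
def rod_pair_factory(rng):
    def make(**kw):
        return random_rod(rng, **kw), random_rod(rng, idx=1, **kw)

    return make


def make_filset(rods, eta=0.01):
    return FilamentSet.from_list(rods, eta=eta)
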