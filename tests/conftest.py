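import numpy as np
import pytest

import segmoco as sm


@pytest.fixture(scope="session")
def phantom32():
    return sm.make_phantom(32, seed=0)


@pytest.fixture(scope="session")
def coils32():
    return sm.make_coil_maps(32, 4, seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_transform(rng, trans=2.0, rot=5.0) -> sm.RigidTransform:
    return sm.RigidTransform(t=tuple(rng.normal(0, trans, 3)),
                             r=tuple(rng.normal(0, rot, 3)))
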