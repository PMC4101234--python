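import numpy as np
import pytest

import nactct as n


@pytest.fixture(scope="session")
def small_setup():
    """32x32 phantom with a 20-view geometry: shared by solver tests."""
    size, nv = 32, 20
    f = n.make_phantom(size)
    geom = n.ProjectionGeometry(angles=n.make_angles(nv), n_detectors=size)
    A = n.build_system_matrix(f.shape, geom)
    p = n.project(A, f)
    return f, A, p


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
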