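import numpy as np
import pytest
import trimesh

from subshape import TriangleMesh, make_template_surface


@pytest.fixture(scope="session")
def hippo_small():
    """Small hippocampus-like template (mesh, analytic grid)."""
    return make_template_surface("hippocampus_like", (30, 40), seed=1)


@pytest.fixture(scope="session")
def amygdala_small():
    return make_template_surface("amygdala_like", (30, 40), seed=1)


@pytest.fixture(scope="session")
def icosphere():
    tm = trimesh.creation.icosphere(subdivisions=4)
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
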