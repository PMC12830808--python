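import numpy as np
import pytest

from growthlines import mesh as gmesh
from growthlines import synthetic


@pytest.fixture(scope="session")
def tube():
    return synthetic.tube()


@pytest.fixture(scope="session")
def small_tube():
    return synthetic.tube(n_axial=8, n_circ=8, length=2.0, radius=0.4)


@pytest.fixture(scope="session")
def sphere():
    """Moderately dense unit icosphere for resolution-limit oracles."""
    return synthetic.unit_sphere(subdivisions=4)


@pytest.fixture(scope="session")
def default_series(tube):
    spec = synthetic.default_deformation(tube, rng_seed=0)
    series, truth = synthetic.generate_stage_series(tube, spec)
    return series, truth


@pytest.fixture()
def two_stage_scaled(small_tube):
    """Two-stage series: base and a uniform x3 scale about the origin."""
    scaled = small_tube.with_vertices(small_tube.vertices * 3.0, stage_label="big")
    return gmesh.StageSeries([small_tube, scaled])
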