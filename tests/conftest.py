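import numpy as np
import pytest

from ceph3d.config import RunConfig
from ceph3d.geometry import build_reference_planes
from ceph3d.landmarks import build_registry
from ceph3d.parameters import build_parameter_registry
from ceph3d.synthetic import make_template, perturb


@pytest.fixture(scope="session")
def registry():
    return build_registry()


@pytest.fixture(scope="session")
def param_registry():
    return build_parameter_registry()


@pytest.fixture(scope="session")
def template():
    """The fixed, exactly mirror-symmetric base head (no shape variation)."""
    return make_template(0, variation_mm=0.0)


@pytest.fixture(scope="session")
def template_planes(template):
    return build_reference_planes(template)


@pytest.fixture(scope="session")
def varied_template():
    """A seeded symmetric head with shape variation."""
    return make_template(7)


@pytest.fixture(scope="session")
def asym_head(template):
    """Asymmetric head with the Frankfort fit points kept coplanar, so the
    geometry stays exactly equivariant under rigid motions/reflections."""
    return perturb(template, sigma_mm=1.0, seed=11, keep_fh_coplanar=True)


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
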