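import numpy as np
import pytest

from anovahd import (
    FeatureMatrix,
    build_kernel,
    center_scale_columns,
    synth_markers,
)
from anovahd.simulation import MarkerPanelSpec


@pytest.fixture(scope="session")
def small_panel():
    """A 120 x 160 binary marker panel with moderate adjacent LD."""
    return synth_markers(MarkerPanelSpec(n=120, p=160, ld_rho=0.5, seed=11))


@pytest.fixture(scope="session")
def small_panel_unit(small_panel):
    return center_scale_columns(small_panel, "unit_variance")


@pytest.fixture(scope="session")
def small_kernel(small_panel):
    return build_kernel(center_scale_columns(small_panel, "span_scaled"))


@pytest.fixture(scope="session")
def wheat_scale_panel():
    """Full-size synthetic stand-in for a 599 x 1,279 inbred marker panel."""
    return synth_markers(MarkerPanelSpec(seed=1))


@pytest.fixture(scope="session")
def wheat_scale_unit(wheat_scale_panel):
    return center_scale_columns(wheat_scale_panel, "unit_variance")


@pytest.fixture(scope="session")
def wheat_scale_kernel(wheat_scale_panel):
    return build_kernel(center_scale_columns(wheat_scale_panel, "span_scaled"))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_feature_matrix(seed, n=12, p=5):
    r = np.random.default_rng(seed)
    return FeatureMatrix(r.standard_normal((n, p)))
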