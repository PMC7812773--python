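import numpy as np
import pytest

from confield import SyntheticConfig, make_aperture, make_mesh


@pytest.fixture(scope="session")
def small_mesh():
    return make_mesh(6, 7, spacing=1.0, hemisphere="L")


@pytest.fixture(scope="session")
def bar_aperture():
    return make_aperture("bar", field_radius=8.0, n_frames=120, grid_res=81)


@pytest.fixture(scope="session")
def tiny_config():
    """A fast-but-complete synthetic configuration for integration tests."""
    return SyntheticConfig(
        mesh_rows=8,
        mesh_cols=10,
        n_runs=4,
        n_timepoints_per_run=120,
        n_targets=20,
        cf_sigma_choices=(2.0, 3.0),
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
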