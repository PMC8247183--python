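import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ecodiff as ed

settings.register_profile(
    "ci", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_landscape():
    """Small all-covariate landscape for fast unit tests."""
    return ed.generate_landscape(seed=5, n_rows=20, n_cols=20, config=ed.StudyConfig(n_rows=20, n_cols=20, min_water_cells=80))


@pytest.fixture(scope="session")
def open_water_landscape():
    """Fully-water 30x30 domain with zeroed covariates (homogeneous medium)."""
    nr = nc = 30
    water = np.ones((nr, nc), dtype=bool)
    covs = {name: np.zeros((nr, nc)) for name in ed.landscape.COVARIATE_NAMES}
    return ed.Landscape(cell_size_m=400.0, water_mask=water, covariates=covs)


def corridor_landscape(n_cols: int, cell_size_m: float = 400.0) -> ed.Landscape:
    """1-D water corridor (single row) with zero covariates."""
    water = np.ones((1, n_cols), dtype=bool)
    covs = {name: np.zeros((1, n_cols)) for name in ed.landscape.COVARIATE_NAMES}
    return ed.Landscape(cell_size_m=cell_size_m, water_mask=water, covariates=covs)


@pytest.fixture(scope="session")
def desk_study():
    """One full synthetic study at the default desk configuration."""
    return ed.generate_study(seed=42)
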