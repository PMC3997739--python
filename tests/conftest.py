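import numpy as np
import pytest

from coralhsm.grid import Grid, GridSpec
from coralhsm.pipeline import run_pipeline
from coralhsm.synthetic_seascape import SeascapeConfig, generate


@pytest.fixture(scope="session")
def default_config() -> SeascapeConfig:
    return SeascapeConfig(seed=1)


@pytest.fixture(scope="session")
def truth(default_config):
    return generate(default_config)


@pytest.fixture(scope="session")
def pipeline_result(default_config):
    """One full pipeline run shared by the integration-level tests."""
    return run_pipeline(
        default_config, with_jackknife=True, with_reports=True, bootstrap_reps=20
    )


@pytest.fixture
def small_spec() -> GridSpec:
    return GridSpec(x0=0.0, y0=0.0, cell_size=500.0, rows=10, cols=10)


@pytest.fixture
def flat_grid(small_spec) -> Grid:
    return Grid(np.full((10, 10), 1000.0), small_spec)
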