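import numpy as np
import pytest

from nutrigrid.grids import Affine, Raster
from nutrigrid.synthetic import ScenarioSpec, generate_scenario


@pytest.fixture(scope="session")
def scenario():
    """One default-scale synthetic world shared across the suite."""
    return generate_scenario(42)


@pytest.fixture(scope="session")
def small_scenario():
    """A small, fast scenario for I/O and CLI round trips."""
    return generate_scenario(7, ScenarioSpec(shape=(24, 24)))


@pytest.fixture(scope="session")
def pipeline_result(scenario):
    from nutrigrid.pipeline import run_stages

    return run_stages(scenario.as_pipeline_inputs(), years=[2020])


@pytest.fixture
def unit_transform():
    return Affine.from_origin(0.0, 10.0, 1.0, 1.0)


@pytest.fixture
def tiny_grid(unit_transform):
    """A 2×3 single-province grid used by hand-computable spatial tests."""

    def make(values, nodata=-9999.0):
        return Raster(np.asarray(values, dtype=np.float64), unit_transform,
                      nodata=nodata)

    return make
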