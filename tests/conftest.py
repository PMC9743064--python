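import numpy as np
import pytest

from sdmax.grid_io import EnvStack, RasterGrid
from sdmax.occurrences import deduplicate, extract_presence_values, fishnet_thin
from sdmax.synthetic import (
    TruthConfig,
    generate_env_stack,
    sample_occurrences,
    true_suitability,
)

HEADER = {
    "nrows": 80, "ncols": 80, "xllcorner": 100.0, "yllcorner": 20.0,
    "cellsize": 0.05, "nodata_value": -9999.0,
}


def make_grid(values, cellsize=1.0, xll=0.0, yll=0.0, nodata=-9999.0, name="var"):
    values = np.asarray(values, dtype=float)
    return RasterGrid(
        ncols=values.shape[1], nrows=values.shape[0], xllcorner=xll, yllcorner=yll,
        cellsize=cellsize, nodata_value=nodata, values=values, variable_name=name,
    )


@pytest.fixture(scope="session")
def truth_config():
    return TruthConfig(seed=0, n_presence=500)


@pytest.fixture(scope="session")
def env_stack(truth_config):
    return generate_env_stack(HEADER, truth_config)


@pytest.fixture(scope="session")
def suitability(env_stack, truth_config):
    return true_suitability(env_stack, truth_config)


@pytest.fixture(scope="session")
def occurrences(suitability, truth_config):
    return sample_occurrences(suitability, truth_config)


@pytest.fixture(scope="session")
def thinned(occurrences, env_stack):
    dedup, _ = deduplicate(occurrences)
    thin, _ = fishnet_thin(dedup, env_stack.template())
    return thin


@pytest.fixture(scope="session")
def presence_table(thinned, env_stack):
    return extract_presence_values(thinned, env_stack)
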