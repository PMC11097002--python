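import numpy as np
import pandas as pd
import pytest

from weedclim.extraction import enrich
from weedclim.occurrences import clean_occurrences, read_occurrences
from weedclim.pipeline import RunConfig, run_all
from weedclim.synthetic import (default_scenario, generate_crop_grids,
                                generate_env_grids, generate_occurrences)


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(seed=1)


@pytest.fixture(scope="session")
def world(scenario):
    """Generated grids, raw occurrences and crop layers for seed 1."""
    grids = generate_env_grids(scenario)
    raw = generate_occurrences(scenario, grids)
    crops = generate_crop_grids(scenario, grids["elev"])
    return {"grids": grids, "raw": raw, "crops": crops, "scenario": scenario}


@pytest.fixture(scope="session")
def enriched(world):
    from tests_support import standardize
    clean, _ = clean_occurrences(standardize(world["raw"]))
    g = world["grids"]
    return enrich(clean, g["lst"], g["rzsm"], g["elev"])


@pytest.fixture(scope="session")
def artifact_dir(tmp_path_factory, scenario):
    """One full pipeline run shared by the end-to-end tests."""
    out = tmp_path_factory.mktemp("run") / "artifacts"
    cfg = RunConfig(output_dir=str(out), seed=1, scenario=default_scenario(1))
    return run_all(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
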