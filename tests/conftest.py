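import json

import numpy as np
import pytest

from csfdyn.pipeline import default_config, run_pipeline
from csfdyn.types import AxialGrid, AxialProfile


@pytest.fixture()
def uniform_profile():
    """Constant-geometry SAS: A_sas = 23.66 mm², P_sas = 38.36 mm."""
    grid = AxialGrid.uniform(300.0, 1.0)
    n = grid.n
    return AxialProfile(
        grid=grid,
        A_c=np.full(n, 14.70),
        A_d=np.full(n, 38.36),
        P_c=np.full(n, 16.00),
        P_d=np.full(n, 22.36),
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run (default synthetic cohort, all stages)."""
    out = tmp_path_factory.mktemp("pipeline")
    manifest = run_pipeline(default_config(), out, seed=0)
    return manifest, out


@pytest.fixture(scope="session")
def battery_meta(pipeline_run):
    manifest, _ = pipeline_run
    return json.loads(manifest.outputs["battery_meta"])
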