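import numpy as np
import pytest

from gonadatlas import synthetic_data as sd


@pytest.fixture(scope="session")
def study_design():
    return sd.build_design("study-mirror", seed=1)


@pytest.fixture(scope="session")
def atlas(study_design):
    """Default synthetic atlas: full truth panel, seed 7."""
    return sd.simulate_atlas(study_design, seed=7)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on the synthetic preset, shared across tests."""
    import json
    import warnings

    from gonadatlas.cli_io import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline") / "run"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        run_pipeline(RunConfig(out_dir=str(out), seed=11))
    with open(out / "run_log.json") as fh:
        log = json.load(fh)
    return out, log


@pytest.fixture
def rng():
    return np.random.default_rng(0)
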