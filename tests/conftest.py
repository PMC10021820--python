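import pytest

from pencost.pipeline import run_pipeline
from pencost.synthetic import (
    expected_outputs,
    pilot_scenario,
    write_scenario_files,
)

PILOT_SEED = 2016


@pytest.fixture(scope="session")
def pilot_config():
    """Noise-free scenario calibrated to the published pilot figures."""
    return pilot_scenario(seed=PILOT_SEED)


@pytest.fixture(scope="session")
def pilot_truth(pilot_config):
    return expected_outputs(pilot_config)


@pytest.fixture(scope="session")
def pilot_files(pilot_config, tmp_path_factory):
    """Generated input CSVs for the pilot scenario."""
    outdir = tmp_path_factory.mktemp("pilot_inputs")
    return write_scenario_files(pilot_config, outdir, seed=PILOT_SEED)


@pytest.fixture(scope="session")
def pilot_result(pilot_files, tmp_path_factory):
    """Full pipeline run on the generated pilot inputs."""
    outdir = tmp_path_factory.mktemp("pilot_outputs")
    return run_pipeline(pilot_files["ledger"], pilot_files["dom"],
                        pilot_files["staffing"],
                        pilot_files["denominators"], outdir=outdir)
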