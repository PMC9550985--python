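import json

import pytest

from ydelseek import pipeline
from ydelseek.pipeline import run_config_from_manifest
from ydelseek.synthdata import simulate_system


@pytest.fixture(scope="session")
def small_config():
    return pipeline.preset_config("gsf-small", seed=3)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_system(small_config)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    pipeline.make_fixture("gsf-small", seed=3, out_dir=out)
    return out


@pytest.fixture(scope="session")
def small_manifest(fixture_dir):
    with open(fixture_dir / "manifest.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def pipeline_run(small_manifest, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_out")
    config = run_config_from_manifest(small_manifest, out)
    report = pipeline.run_all(config)
    return report, out
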