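import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """One default fixture set shared by the slower integration tests."""
    from tfnetminer.synthetic_fixtures import FixtureConfig, generate_all

    out = tmp_path_factory.mktemp("fixture")
    truth = generate_all(FixtureConfig(seed=11), out)
    return out, truth


@pytest.fixture(scope="session")
def pipeline_run(fixture_dir, tmp_path_factory):
    """One completed pipeline run on the shared fixture."""
    from tfnetminer.pipeline import PipelineConfig, run_pipeline

    fdir, truth = fixture_dir
    out = tmp_path_factory.mktemp("run")
    manifest = run_pipeline(PipelineConfig.from_fixture_dir(fdir, out))
    return out, truth, manifest
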