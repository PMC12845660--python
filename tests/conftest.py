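import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_design():
    from fluorscreen.simulate import StudyDesign
    return StudyDesign(seed=7)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on the default synthetic study, shared."""
    from fluorscreen.pipeline import PipelineConfig, run_pipeline
    out = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(out_dir=str(out), seed=11)
    outputs = run_pipeline(cfg)
    return cfg, outputs
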