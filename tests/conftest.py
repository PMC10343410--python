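import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """The synthetic study generated once per session: fixture definition,
    generated runs, and the full screening result."""
    from pomscreen.pipeline import PipelineParams, run_screening
    from pomscreen.simulate import generate_run, study_fixture

    fx = study_fixture(seed=1)
    runs = [generate_run(recipe) for recipe in fx.recipes]
    params = PipelineParams(seed=1)
    result = run_screening(runs, fx.suspects, fx.msp_library, fx.standards, params)
    return {"fixture": fx, "runs": runs, "params": params, "result": result}
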