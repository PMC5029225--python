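import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def worked_example():
    """The fixed 6-module / 12-ortholog / 4v4 fixture."""
    from modquant import make_worked_example

    return make_worked_example()


@pytest.fixture(scope="session")
def worked_profile(worked_example):
    from modquant import quantify_all

    db, matrix, _ = worked_example
    return quantify_all(db, matrix)
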