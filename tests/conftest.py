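import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def fixture_w1():
    from bdellocomp import make_fixture

    return make_fixture("W1_enrichment")


@pytest.fixture(scope="session")
def fixture_w1_matrix(fixture_w1):
    from bdellocomp import build_presence_matrix

    return build_presence_matrix(
        fixture_w1.annotations, genomes=list(fixture_w1.metadata["genome_id"])
    )
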