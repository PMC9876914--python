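import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from ssmap import simulate  # noqa: E402


@pytest.fixture(scope="session")
def small_genome():
    """Two 150-kb chromosomes: enough structure for fast population tests."""
    return simulate.GenomeSpec(
        chromosomes=(("chrA", 150_000), ("chrB", 150_000)),
        gc_fraction=0.4,
        seed=11,
    )
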