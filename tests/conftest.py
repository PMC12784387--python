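import pytest
from hypothesis import HealthCheck, settings

from heritagems import AssemblySpec, default_library, generate_library

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def candidate_libraries(library):
    """Candidate-ion libraries per family selection, generated once."""
    cache = {}

    def get(*families: str):
        key = tuple(sorted(families))
        if key not in cache:
            cache[key] = generate_library(library, AssemblySpec(families=key))
        return cache[key]

    return get
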