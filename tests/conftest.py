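from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

from dabquant import RunConfig, SyntheticSlideSpec, generate_slide
from dabquant.validation import SMALL_SLIDE_SPEC

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSlideSpec:
    return SMALL_SLIDE_SPEC


@pytest.fixture(scope="session")
def noise_free_bundle(small_spec):
    """One noise-free small slide shared by read-only tests."""
    return generate_slide(replace(small_spec, noise_sd=0.0, seed=7))
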