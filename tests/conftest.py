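import pytest

from shockbia.io import RunConfig
from shockbia.simulator import SubjectParams


@pytest.fixture
def noise_free_params() -> SubjectParams:
    return SubjectParams(noise_cv=0.0, vitals_noise_cv=0.0)


@pytest.fixture
def default_config() -> RunConfig:
    return RunConfig()
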