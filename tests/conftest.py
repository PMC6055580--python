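import pytest

from daphnia_ifd.column import build_column, treatment_environment
from daphnia_ifd.ibm import (
    AgeClassParams,
    ModelParams,
    default_params,
)
from daphnia_ifd.rates import PerceptionParams


@pytest.fixture(scope="session")
def column():
    return build_column()


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def sharp_params(params):
    """Default parameterization with zero perception thresholds
    (omniscient animals)."""
    zero = PerceptionParams(0.0, 0.0)
    return ModelParams(
        juvenile=AgeClassParams(
            params.juvenile.growth, params.juvenile.rd, zero, params.juvenile.gamma
        ),
        adult=AgeClassParams(
            params.adult.growth, params.adult.rd, zero, params.adult.gamma
        ),
        mortality=params.mortality,
        handling=params.handling,
        n_exponent=params.n_exponent,
    )


@pytest.fixture(scope="session")
def environments():
    return {tr: treatment_environment(tr) for tr in ("none", "food", "risk", "both")}
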