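import hypothesis
import pytest

from wpmdyn import ParameterSet

# the parameter-set fixtures are pure value constructors, safe to reuse
# across hypothesis examples
hypothesis.settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[hypothesis.HealthCheck.function_scoped_fixture],
)
hypothesis.settings.load_profile("default")


@pytest.fixture
def set_a() -> ParameterSet:
    """Worked-example rates with BR = 0.743 < 1 (debris dies out)."""
    return ParameterSet(lambda_=0.36, gamma=0.41, beta=0.15, mu=0.4, alpha=0.65, theta=0.15)


@pytest.fixture
def set_b() -> ParameterSet:
    """Worked-example rates with BR = 7.5429 > 1 (debris persists)."""
    return ParameterSet(lambda_=0.66, gamma=0.21, beta=0.4, mu=0.4, alpha=0.5, theta=0.2)


@pytest.fixture
def table1() -> ParameterSet:
    """Rates of the sensitivity worked example (BR = 42.4286)."""
    return ParameterSet(lambda_=0.66, gamma=0.21, beta=0.75, mu=0.4, alpha=0.5, theta=0.05)


@pytest.fixture
def set_d() -> ParameterSet:
    """Rates with alpha = gamma and BR > 1, where the Lyapunov certificate applies."""
    return ParameterSet(lambda_=0.66, gamma=0.5, beta=0.4, mu=0.4, alpha=0.5, theta=0.2)
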