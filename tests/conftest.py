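import pytest
from hypothesis import HealthCheck, settings

from patchforage import AgentPolicy, RatRecord, TaskConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def mvt_rat() -> RatRecord:
    return RatRecord("MVT1", "male", 0.40, AgentPolicy("mvt_optimal"))


def make_hyperbolic_rat(k: float, b: float, rat_id: str = "H1", sex: str = "male",
                        weight: float = 0.40, **kw) -> RatRecord:
    return RatRecord(rat_id, sex, weight,
                     AgentPolicy("hyperbolic_discounter", k=k, b=b, **kw))
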