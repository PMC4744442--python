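import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160206)


def random_expression(rng, n, p):
    """Random expression block with generic ids."""
    from sdrgsa import ExpressionMatrix

    return ExpressionMatrix(
        rng.standard_normal((n, p)) * rng.uniform(0.5, 2.0, p) + rng.normal(0, 1, p),
        [f"g{j}" for j in range(p)],
        [f"s{i}" for i in range(n)],
    )
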