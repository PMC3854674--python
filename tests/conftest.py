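import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def q_grid():
    from twovar import default_q_grid

    return default_q_grid()


@pytest.fixture(scope="session")
def reference_table_8_15():
    """Monte-Carlo f(X, L, n) reference at the n=8, X=15 showcase condition."""
    from twovar import mc_probability_curve

    return mc_probability_curve(8, 15, reps=10_000, seed=20_240_815)
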