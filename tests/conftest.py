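import pytest
from hypothesis import HealthCheck, settings

from gcdesign import DesignEvaluator, FluxEvaluator, SearchConfig
from gcdesign.fixtures import toy_redox_model

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy():
    return toy_redox_model()


@pytest.fixture(scope="session")
def toy_flux(toy):
    return FluxEvaluator(toy)


@pytest.fixture(scope="session")
def rid(toy):
    """Reaction id -> column index shortcut for the toy model."""
    return {r: j for j, r in enumerate(toy.reaction_ids)}


@pytest.fixture()
def exact_cfg():
    """Search config whose guarantees are exact on the toy model:
    no growth tolerance and a fine envelope grid."""
    return SearchConfig(
        k_max=2, pop_size=20, max_generations=50, tau=0.0, n_env=50, seed=0
    )


@pytest.fixture()
def toy_evaluator(toy, exact_cfg):
    return DesignEvaluator(toy, exact_cfg)
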