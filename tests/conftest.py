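import pytest
from hypothesis import HealthCheck, settings

from txorder.pipeline import run_full_analysis
from txorder.synthetic_data import SimulationConfig, simulate_study

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A fast study: 800 genes, 12 regulons, same condition layout as the default."""
    kwargs = dict(
        n_genes=800,
        n_coupled=80,
        n_networks=12,
        n_coupled_networks=3,
        coupled_regulon_size=(16, 18),
        regulatees_per_network=(16, 60),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config())


@pytest.fixture(scope="session")
def default_study():
    """The full default study (the conditions every end-to-end check assumes)."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_study):
    return run_full_analysis(
        default_study.expression,
        default_study.conditions,
        default_study.annotation,
        default_study.networks,
    )
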