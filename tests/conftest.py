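import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def default_params():
    from apiarisk.profit import ProfitParameters

    return ProfitParameters()


@pytest.fixture
def tiny_config():
    """Two near + two far sites, three compounds, one year — fast and exact."""
    from apiarisk.synthetic import CompoundSpec, SyntheticConfig

    return SyntheticConfig(
        n_near_sites=2,
        n_far_sites=2,
        years=("2021",),
        compounds=(
            CompoundSpec(name="thiamethoxam", detection_prob=0.8, far_site_multiplier=3.0),
            CompoundSpec(name="clothianidin", detection_prob=0.5, far_site_multiplier=4.0),
            CompoundSpec(name="boscalid", detection_prob=0.9, log_mean_pollen=2.0),
        ),
        seed=11,
    )
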