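import pytest
from hypothesis import HealthCheck, settings

from dpcsig import SimConfig, generate_dataset

settings.register_profile(
    "deterministic", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


def small_config(**overrides) -> SimConfig:
    """Compact geometry used throughout the unit tests: fast but structured."""
    fields = dict(n_participants=20, trials_per_participant=8, n_parcels=40,
                  n_signal_parcels=8, n_timepoints=12, snr=2.0, seed=11)
    fields.update(overrides)
    return SimConfig(**fields)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def null_dataset():
    """Complete null: no planted signal, no rating/trait coupling."""
    return generate_dataset(small_config(
        seed=17, snr=0.0, rating_slope=0.0,
        trait_slopes={"loneliness": 0.0, "life_satisfaction": 0.0,
                      "support_count": 0.0}))
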