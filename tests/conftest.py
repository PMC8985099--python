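import pytest
from hypothesis import HealthCheck, settings

from ssp_ams.synthetic_data import SimConfig, generate_all, strong_effect_config

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def small_sim_config(**overrides) -> SimConfig:
    """A fast 12-species world for unit tests (seconds, not minutes)."""
    base = dict(
        n_species=12,
        frac_ams=0.5,
        proteins_per_species=(250, 300),
        frac_true_ssp=0.10,
        n_orthogroups=80,
        n_planted_specific=2,
        n_planted_preferential=2,
        preferential_effect=3.0,
        n_de_species=2,
        n_replicates=3,
        n_planted_convergent_up=1,
        n_planted_convergent_down=1,
        planted_module_size=4,
        n_planted_modules=1,
        rng_seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    """Noisy-tool small dataset shared by io/round-trip tests."""
    return generate_all(small_sim_config())


@pytest.fixture(scope="session")
def strong_small_dataset():
    """Noiseless small dataset: perfect tools, strong effects."""
    cfg = small_sim_config(
        tool_sensitivity=1.0,
        tool_specificity=1.0,
        frac_incomplete_orf=0.0,
        n_replicates=5,
        de_log2fc=5.0,
        module_pcc=0.995,
    )
    return generate_all(cfg)


@pytest.fixture(scope="session")
def strong_full_dataset():
    """Full-scale (60-species) noiseless dataset for recovery checks."""
    return generate_all(strong_effect_config(rng_seed=0))
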