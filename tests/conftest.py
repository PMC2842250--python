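import pytest
from hypothesis import HealthCheck, settings

from stressarray import pipeline as pl
from stressarray import synthetic as syn

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_contexts():
    """Scaled-down three-stimulus design (400 genes) preserving the study's
    effect structure: distinct per-stimulus up/down fractions and dependency
    probabilities spanning the reported range."""
    return (
        syn.StressContext("TNFa", 45, frac_up=30 / 400, frac_down=8 / 400,
                          dep_fraction=0.60, dep_fraction_down=1.0),
        syn.StressContext("anisomycin", 45, frac_up=32 / 400, frac_down=10 / 400,
                          dep_fraction=0.75, dep_fraction_down=1.0),
        syn.StressContext("NaCl", 120, frac_up=36 / 400, frac_down=6 / 400,
                          dep_fraction=0.85, dep_fraction_down=0.70),
    )


def small_config(seed: int = 0, **overrides) -> syn.SyntheticConfig:
    base = dict(
        contexts=small_contexts(), seed=seed, n_genes=400, n_probes=900,
        core_size=5, n_go_terms=9, go_term_size_range=(20, 60),
        enriched_term_size=25, enrichment_factor=2.0,
        tf_term_size=30, tf_enrichment_factor=2.0,
    )
    base.update(overrides)
    return syn.SyntheticConfig(**base)


@pytest.fixture(scope="session")
def zero_noise_small_run() -> pl.SyntheticRun:
    cfg = small_config(seed=5, channel_noise_sd=0.0, background_mean=0.0)
    return pl.run_synthetic(cfg)


@pytest.fixture(scope="session")
def noisy_small_run() -> pl.SyntheticRun:
    return pl.run_synthetic(small_config(seed=6))


@pytest.fixture(scope="session")
def zero_noise_full_run() -> pl.SyntheticRun:
    """Full-scale (19,261 genes / 41,175 probes) noise-free study."""
    cfg = syn.treatment_config(seed=11, channel_noise_sd=0.0, background_mean=0.0)
    return pl.run_synthetic(cfg, with_annotation=False)
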