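import pytest

from lifemeth import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def spiked_bundle():
    """Synthetic cohort with 10 spiked probes (Δβ=0.05) and one 5-probe
    spiked region (Δβ=0.08) among 4000 probes, n=400."""
    cfg = SimulationConfig(
        n_samples=400,
        n_probes=4000,
        n_spiked_probes=10,
        spike_delta_beta=0.05,
        n_spiked_regions=1,
        region_n_probes=5,
        region_delta_beta=0.08,
        seed=42,
    )
    phenotype, methylation, truth = simulate_bundle(cfg)
    return cfg, phenotype, methylation, truth


@pytest.fixture(scope="session")
def null_bundle():
    """Signal-free synthetic cohort: no spiked probes or regions."""
    cfg = SimulationConfig(
        n_samples=200,
        n_probes=2000,
        n_spiked_probes=0,
        n_spiked_regions=0,
        seed=7,
    )
    phenotype, methylation, truth = simulate_bundle(cfg)
    return cfg, phenotype, methylation, truth
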