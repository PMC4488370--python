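import pytest

from svmicroevo.synthetic_data import SimulationConfig, plant_svs, simulate_genome


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(seed=7, genome_length=2_000_000, n_genes=400,
                            n_deletions=10, n_duplications=6,
                            sv_size_range=(2000, 50_000))


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    assembly, genes = simulate_genome(small_cfg)
    truth = plant_svs(small_cfg, assembly)
    return assembly, genes, truth
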