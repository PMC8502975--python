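import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from bacpan.simulate import SimulationConfig, simulate_strains
from bacpan.align import all_vs_all
from bacpan.cluster import cluster_families, build_matrix


@pytest.fixture(scope="session")
def default_panel():
    """One fully simulated 6-strain panel reused across test modules."""
    cfg = SimulationConfig(seed=2)
    proteomes, genomes, truth = simulate_strains(cfg)
    return cfg, proteomes, genomes, truth


@pytest.fixture(scope="session")
def clustered_panel(default_panel):
    """The default panel pushed through similarity search and clustering."""
    cfg, proteomes, genomes, truth = default_panel
    hits = all_vs_all(proteomes)
    universe = [g for p in proteomes for g in p.genes]
    families = cluster_families(hits, universe)
    matrix = build_matrix(families, [p.strain_id for p in proteomes])
    return cfg, proteomes, genomes, truth, hits, families, matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
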