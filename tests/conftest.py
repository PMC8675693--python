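import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from promoterpop.panel_io import GenomicRegion, HaplotypePanel, PopulationMap
from promoterpop.haplotypes import SnpTriplet
from promoterpop.synthetic_data import SimConfig, simulate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_panel(sequences, populations, positions=None, region=None):
    """Hand-built panel: one sequence string per haplotype (two per sample).

    ``populations`` lists one (subpop, metapop) pair per *sample*.
    """
    n = len(sequences)
    assert n % 2 == 0 and len(populations) == n // 2
    length = len(sequences[0])
    positions = np.arange(1, length + 1) * 100 if positions is None else np.asarray(positions)
    region = region or GenomicRegion("15", 1, int(positions[-1]) + 100, "test")
    samples = {f"S{i:03d}": populations[i] for i in range(n // 2)}
    hap_ids = [f"S{i:03d}.{k}" for i in range(n // 2) for k in (0, 1)]
    matrix = np.array([list(s) for s in sequences], dtype="<U1")
    return HaplotypePanel(region, positions, matrix, hap_ids, PopulationMap(samples))


@pytest.fixture(scope="session")
def sim_dataset():
    """One default synthetic study, shared across tests (read-only)."""
    return simulate_dataset(SimConfig(seed=20210925))


@pytest.fixture(scope="session")
def sim_triplet(sim_dataset):
    return SnpTriplet(positions=sim_dataset.config.promoter_positions)
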