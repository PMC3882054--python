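import numpy as np
import pytest

from recmap.genes import make_causal_cluster, make_toy_gene
from recmap.simulate import SimConfig, build_population, emit_wgs_callset


@pytest.fixture(scope="session")
def default_population():
    """One default-config population, shared across tests (seed 1)."""
    cfg = SimConfig()
    ped, haps = build_population(cfg, seed=1)
    return cfg, ped, haps


@pytest.fixture(scope="session")
def toy_gene():
    return make_toy_gene(np.random.default_rng(7))


@pytest.fixture(scope="session")
def causal_cluster(toy_gene):
    return make_causal_cluster(toy_gene)


@pytest.fixture(scope="session")
def wgs_cohorts(default_population):
    """Case/carrier/noncarrier sample ids for the resequencing design."""
    _, ped, _ = default_population
    cases = ped.affected_ids()[:4]
    carriers = [c for c in ped.carrier_ids() if c not in cases][:6]
    noncarriers = [
        i for i in ped.noncarrier_ids() if ped[i].phenotype == "unaffected"
    ][:8]
    return cases, carriers, noncarriers


@pytest.fixture(scope="session")
def wgs_callset(default_population, toy_gene, causal_cluster, wgs_cohorts):
    cfg, ped, haps = default_population
    cases, carriers, noncarriers = wgs_cohorts
    samples = cases + carriers + noncarriers
    variants, catalogue, truth = emit_wgs_callset(
        haps, toy_gene, causal_cluster, cfg, seed=11, sample_ids=samples
    )
    return variants, catalogue, truth
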