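import pytest

from meiostab import simulate as sim


@pytest.fixture(scope="session")
def asy3_td_set():
    return sim.build_allele_set(sim.DEFAULT_GENES["ASY3"], seed=1)


@pytest.fixture(scope="session")
def prd3_set():
    return sim.build_allele_set(sim.DEFAULT_GENES["PRD3"], seed=1)


@pytest.fixture(scope="session")
def zyp1b_set():
    return sim.build_allele_set(sim.DEFAULT_GENES["ZYP1b"], seed=1)


@pytest.fixture(scope="session")
def small_population():
    """Study-sized tetraploid population with read counts at moderate depth."""
    genes = {"ASY3": sim.DEFAULT_CLASS_FREQS["ASY3"], "ZYP1b": (0.0, 1.0, 0.0)}
    truth = sim.simulate_population(52, genes, seed=42)
    sets = {g: sim.build_allele_set(sim.DEFAULT_GENES[g], 42) for g in genes}
    sites = {g: s.diag_sites for g, s in sets.items()}
    counts = sim.simulate_read_counts(truth, sites, depth=500, error_rate=0.01, seed=42)
    return truth, sites, counts
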