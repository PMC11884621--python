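import pytest

from globintyper import (
    build_mini_reference,
    default_allele_catalog,
    default_panel,
)


@pytest.fixture(scope="session")
def mini():
    return build_mini_reference(seed=101)


@pytest.fixture(scope="session")
def panel(mini):
    return default_panel(mini)


@pytest.fixture(scope="session")
def catalog(mini):
    return default_allele_catalog(mini)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-sample error-free cohort genotyped end to end (shared across tests)."""
    from globintyper import simulate_cohort
    from globintyper.pipeline import genotype_cohort

    sim = simulate_cohort(
        12, seed=42, depth=20, sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
        ensure_het_amplicon="HBG",
    )
    results = genotype_cohort(
        sim.reads, sim.panel, sim.mini.contigs, sim.catalog, mini=sim.mini
    )
    return sim, results
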