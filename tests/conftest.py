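import pytest

from redundohist import (
    GeneFamilySpec,
    GeneModel,
    HistoneClass,
    HistoneFamily,
    SimulationConfig,
    simulate_cohort,
    synthetic_signature_catalog,
)


@pytest.fixture(scope="session")
def catalog3():
    """Three well-separated synthetic SBS96 signatures."""
    return synthetic_signature_catalog(n_signatures=3, seed=11)


@pytest.fixture(scope="session")
def mixture():
    return {"all": {"SYN1": 0.6, "SYN2": 0.3, "SYN3": 0.1}}


@pytest.fixture(scope="session")
def sim(catalog3, mixture):
    """A 200-patient cohort with known signature mixture and flat multipliers."""
    config = SimulationConfig(seed=42, n_patients=200, signature_mixture=mixture)
    return simulate_cohort(config, catalog3)


@pytest.fixture(scope="session")
def big_sim(catalog3, mixture):
    """A cohort large enough (~50k SNVs) for signature-recovery checks."""
    config = SimulationConfig(seed=77, n_patients=1100, signature_mixture=mixture)
    return simulate_cohort(config, catalog3)


@pytest.fixture
def toy_registry():
    """Two genes sharing one protein plus two singletons."""
    return [
        GeneModel("HA1", "PROT_A", 300, HistoneFamily.H4, HistoneClass.CANONICAL, "6"),
        GeneModel("HA2", "PROT_A", 600, HistoneFamily.H4, HistoneClass.CANONICAL, "6"),
        GeneModel("HB1", "PROT_B", 411, HistoneFamily.H3, HistoneClass.CANONICAL, "6"),
        GeneModel("GX1", "PROT_X", 1500),
    ]


@pytest.fixture
def two_gene_spec():
    """Equal-length two-gene registry spec for multiplier experiments."""
    return [
        GeneFamilySpec("PA", 1, 1500, HistoneFamily.H4, HistoneClass.CANONICAL,
                       "6", "GENEA"),
        GeneFamilySpec("PB", 1, 1500, HistoneFamily.NON_HISTONE,
                       HistoneClass.NOT_APPLICABLE, "2", "GENEB"),
    ]
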