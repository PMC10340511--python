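"""Do genes encoding the same protein carry mutations uniformly?

For each multi-gene protein the observed patients-with-a-mutation per gene
are tested against expectations proportional to CDS length with a
goodness-of-fit chi-squared; sparse tables (any expected cell < 5) switch to
a Monte-Carlo p-value (10,000 simulated tables). q-values control the FDR
across proteins within each cancer type.
"""

from redundohist import SimulationConfig, simulate_cohort, synthetic_signature_catalog
from redundohist.homogeneity import homogeneity_scan

catalog = synthetic_signature_catalog(3, seed=11)
# Plant a hot gene inside the 11-gene H4 family: H4C1 mutates 8x faster
config = SimulationConfig(
    seed=7, n_patients=400,
    per_gene_rate_multiplier={"H4C1": 8.0},
    signature_mixture={"all": {"SYN1": 0.6, "SYN2": 0.3, "SYN3": 0.1}},
)
sim = simulate_cohort(config, catalog)

scan = homogeneity_scan(sim.variants, sim.registry, clinical=sim.clinical,
                        n_sim=10_000, seed=1)
pan = scan[scan["cancer_type"] == "pan-cancer"]
print(pan[["protein_accession", "n_genes", "total_patients_mutated",
           "method", "chi2", "p", "q"]].to_string(index=False))
print("\nP62805 is the 11-gene H4 family carrying the planted 8x gene: its")
print("q-value should be far below 0.05, while the undisturbed families are")
print("consistent with length-proportional uniformity. 'monte_carlo' marks")
print("sparse tables where the asymptotic chi-squared is not trusted.")
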