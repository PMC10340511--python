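"""Synthetic cohort generator: determinism, conservation, designed effects."""

import numpy as np
import pytest

from redundohist import (
    GeneModel,
    SimulationConfig,
    io,
    make_registry,
    simulate_cohort,
    simulate_cooccurrence_cohort,
    simulate_reference,
    synthetic_signature_catalog,
)
from redundohist.simulate import default_registry_spec, solve_joint_probability


class TestReference:
    def test_deterministic_given_seed(self):
        registry = [GeneModel("G1", "P1", 12)]
        ref1 = simulate_reference(registry, seed=5)
        ref2 = simulate_reference(registry, seed=5)
        assert ref1 == ref2
        assert len(ref1["G1"]) == 12
        assert set(ref1["G1"]) <= set("ACGT")

    def test_gc_content_at_scale(self):
        # 100 kb at target 0.5: binomial CI keeps observed GC within [0.47, 0.53]
        registry = [GeneModel("G1", "P1", 100_000)]
        seq = simulate_reference(registry, seed=3, gc_content=0.5)["G1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.47 <= gc <= 0.53

    def test_short_cds_rejected(self):
        with pytest.raises(ValueError, match="cds_length"):
            simulate_reference([GeneModel("G1", "P1", 5)], seed=1)


class TestCohort:
    def test_conservation_of_mutation_count(self, sim):
        burdens = sim.ground_truth["per_patient_burden"]
        assert len(sim.variants) == sum(burdens.values())
        assert len(sim.variants) == sim.ground_truth["n_mutations"]
        per_gene = sim.ground_truth["per_gene_counts"]
        assert sum(per_gene.values()) == len(sim.variants)

    def test_same_seed_gives_byte_identical_maf(self, tmp_path, catalog3, mixture):
        config = SimulationConfig(seed=9, n_patients=30,
                                  signature_mixture=mixture)
        paths = []
        for name in ("a.maf", "b.maf"):
            result = simulate_cohort(config, catalog3)
            io.write_variants_maf(result.variants, tmp_path / name)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_rate_multiplier_shifts_gene_counts(self, two_gene_spec, catalog3):
        # 10x multiplier on an equal-length pair: expect count ratio in [8, 12.5]
        config = SimulationConfig(
            seed=21, n_patients=200, registry_spec=two_gene_spec,
            per_gene_rate_multiplier={"GENEA": 10.0},
            signature_mixture={"all": {"SYN1": 0.6, "SYN2": 0.4}},
        )
        result = simulate_cohort(config, catalog3)
        counts = result.ground_truth["per_gene_counts"]
        assert counts["GENEA"] + counts["GENEB"] >= 8_000
        ratio = counts["GENEA"] / counts["GENEB"]
        assert 8.0 <= ratio <= 12.5

    def test_empirical_profile_matches_effective_mixture(self, big_sim):
        # availability-corrected mixture is the channel law of the generator
        from redundohist import build_profile
        sim = big_sim
        snvs = [v for v in sim.variants if v.is_snv]
        assert len(snvs) >= 50_000
        profile, _ = build_profile(snvs)
        eff = sim.ground_truth["effective_mixture"]
        genes = {g.gene_symbol: g for g in sim.registry}
        weights = sim.ground_truth["per_gene_selection_prob"]
        w_hist = sum(w for g, w in weights.items() if genes[g].is_histone)
        expected = w_hist * eff["histone"] + (1 - w_hist) * eff["non_histone"]
        tv = 0.5 * np.abs(profile.normalized - expected).sum()
        assert tv <= 0.03

    def test_hypermutators_get_heavier_burdens(self, catalog3, mixture):
        config = SimulationConfig(
            seed=4, n_patients=300, signature_mixture=mixture,
            hypermutator_fraction=0.1, hypermutator_signature="SYN3",
        )
        result = simulate_cohort(config, catalog3)
        burdens = result.ground_truth["per_patient_burden"]
        hyper = set(result.ground_truth["hypermutators"])
        assert hyper
        mean_h = np.mean([burdens[p] for p in hyper])
        mean_n = np.mean([b for p, b in burdens.items() if p not in hyper])
        assert mean_h > 3 * mean_n

    def test_gene_without_eligible_sites_is_named(self):
        from redundohist.model import SignatureCatalog
        one_hot = np.zeros((96, 1))
        one_hot[0, 0] = 1.0  # all mass on the A[C>A]A channel (context ACA)
        catalog = SignatureCatalog(matrix=one_hot, signature_names=["ONEHOT"])
        registry = make_registry(default_registry_spec(n_background=0))
        reference = simulate_reference(registry, seed=1)
        reference["H4C1"] = "A" * 312  # contains neither ACA nor TGT
        config = SimulationConfig(seed=1, n_patients=5,
                                  signature_mixture={"all": {"ONEHOT": 1.0}})
        with pytest.raises(ValueError, match="H4C1"):
            simulate_cohort(config, catalog, registry=registry,
                            reference=reference)


class TestCooccurrenceDesign:
    def test_joint_probability_reproduces_odds_ratio(self):
        for pq, ph, orr in [(0.15, 0.25, 6.0), (0.3, 0.3, 1.0), (0.1, 0.4, 0.5)]:
            a = solve_joint_probability(pq, ph, orr)
            b, c = pq - a, ph - a
            d = 1 - pq - ph + a
            assert min(a, b, c, d) >= -1e-12
            if orr != 1.0:
                assert (a * d) / (b * c) == pytest.approx(orr, rel=1e-9)
            else:
                assert a == pytest.approx(pq * ph)

    def test_cohort_realizes_designed_table(self):
        result = simulate_cooccurrence_cohort(n_patients=1000, odds_ratio=6.0,
                                              seed=8)
        (a, b), (c, d) = result.ground_truth["realized_table"]
        assert a + b + c + d == 1000
        # every patient observed through at least the background call
        assert len({v.patient_id for v in result.variants}) == 1000
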