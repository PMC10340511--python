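"""Mutation counting and the pooled per-protein rate statistic."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from redundohist import (
    GeneModel,
    GeneMutationCount,
    ProteinGroup,
    VariantClass,
    VariantRecord,
    count_mutations,
    protein_rate,
)
from redundohist.rates import deduplicate, eligible_cancer_types


def _variant(patient, gene, pos, cls, ct="ca"):
    return VariantRecord(patient, gene, "1", pos, "C", "T", cls, cancer_type=ct)


class TestCountMutations:
    REGISTRY = [GeneModel("A", "PA", 300), GeneModel("B", "PB", 600)]

    def test_two_missense_one_patient(self):
        variants = [_variant("P1", "A", 10, VariantClass.MISSENSE),
                    _variant("P1", "A", 20, VariantClass.MISSENSE)]
        counts = {c.gene_symbol: c for c in count_mutations(variants, self.REGISTRY)}
        assert counts["A"].m == 2
        assert counts["A"].patients_mutated == 1

    def test_other_class_contributes_nothing(self):
        variants = [_variant("P1", "A", 10, VariantClass.OTHER)]
        counts = {c.gene_symbol: c for c in count_mutations(variants, self.REGISTRY)}
        assert counts["A"].m == 0

    @pytest.mark.parametrize("cls", sorted(
        (c for c in VariantClass if c is not VariantClass.OTHER),
        key=lambda c: c.value))
    def test_each_of_the_nine_classes_counts(self, cls):
        ref, alt = ("C", "T") if cls.value not in (
            "frameshift_insertion", "frameshift_deletion") else ("C", "-")
        v = VariantRecord("P1", "A", "1", 10, ref, alt, cls)
        counts = {c.gene_symbol: c for c in count_mutations([v], self.REGISTRY)}
        assert counts["A"].m == 1

    def test_three_patients_one_silent_each(self):
        variants = [_variant(f"P{i}", "A", 10 + i, VariantClass.SILENT)
                    for i in range(3)]
        counts = {c.gene_symbol: c for c in count_mutations(variants, self.REGISTRY)}
        assert counts["A"].m == 3
        assert counts["A"].patients_mutated == 3

    def test_exact_duplicates_removed(self):
        v = _variant("P1", "A", 10, VariantClass.MISSENSE)
        kept, removed = deduplicate([v, v])
        assert len(kept) == 1 and removed == 1
        counts = {c.gene_symbol: c for c in count_mutations([v, v], self.REGISTRY)}
        assert counts["A"].m == 1

    def test_cancer_type_filter(self):
        variants = [_variant("P1", "A", 10, VariantClass.MISSENSE, ct="x"),
                    _variant("P2", "A", 20, VariantClass.MISSENSE, ct="y")]
        counts = {c.gene_symbol: c
                  for c in count_mutations(variants, self.REGISTRY, cancer_type="x")}
        assert counts["A"].m == 1


class TestProteinRate:
    def test_hand_arithmetic_two_genes(self):
        group = ProteinGroup("P", (GeneModel("A", "P", 300),
                                   GeneModel("B", "P", 600)))
        counts = [GeneMutationCount("A", "pan-cancer", 2, 1),
                  GeneMutationCount("B", "pan-cancer", 4, 2)]
        rate = protein_rate(group, counts)
        assert rate.m_total == 6 and rate.c_total == 900
        assert rate.r == pytest.approx(6 / 900)

    def test_zero_mutations_zero_rate(self):
        group = ProteinGroup("P", (GeneModel("A", "P", 300),))
        rate = protein_rate(group, [GeneMutationCount("A", "pan-cancer", 0, 0)])
        assert rate.r == 0.0

    def test_eleven_gene_family(self):
        group = ProteinGroup("P62805",
                             tuple(GeneModel(f"H4C{i}", "P62805", 312)
                                   for i in range(1, 12)))
        counts = [GeneMutationCount(f"H4C{i}", "pan-cancer", 1, 1)
                  for i in range(1, 12)]
        rate = protein_rate(group, counts)
        assert rate.m_total == 11 and rate.c_total == 3432
        assert rate.r == pytest.approx(11 / 3432)

    @given(
        data=st.lists(
            st.tuples(st.integers(min_value=0, max_value=50),
                      st.integers(min_value=10, max_value=5000)),
            min_size=1, max_size=12,
        )
    )
    @settings(derandomize=True, max_examples=200)
    def test_mediant_inequality(self, data):
        """Pooled rate lies between the min and max per-gene rates."""
        genes = tuple(GeneModel(f"G{i}", "P", c) for i, (_m, c) in enumerate(data))
        group = ProteinGroup("P", genes)
        counts = [GeneMutationCount(f"G{i}", "pan-cancer", m, min(m, 1))
                  for i, (m, _c) in enumerate(data)]
        rate = protein_rate(group, counts)
        per_gene = [Fraction(m, c) for m, c in data]
        assert min(per_gene) <= Fraction(rate.m_total, rate.c_total) <= max(per_gene)

    @given(k=st.integers(min_value=1, max_value=5),
           m=st.integers(min_value=0, max_value=20),
           c=st.integers(min_value=10, max_value=1000))
    @settings(derandomize=True, max_examples=50)
    def test_scale_invariance_under_family_replication(self, k, m, c):
        """Replicating every member k times leaves r unchanged."""
        base = ProteinGroup("P", (GeneModel("G0", "P", c),))
        replicated = ProteinGroup("P", tuple(GeneModel(f"G{i}", "P", c)
                                             for i in range(k)))
        counts1 = [GeneMutationCount("G0", "pan-cancer", m, min(m, 1))]
        countsk = [GeneMutationCount(f"G{i}", "pan-cancer", m, min(m, 1))
                   for i in range(k)]
        assert protein_rate(base, counts1).r == pytest.approx(
            protein_rate(replicated, countsk).r)


def test_eligible_cancer_types_threshold():
    clinical = {f"P{i}": "common" for i in range(10)}
    clinical.update({f"Q{i}": "rare" for i in range(9)})
    assert eligible_cancer_types(clinical, min_patients=10) == {"common"}
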