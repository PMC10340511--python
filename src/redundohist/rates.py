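"""Mutation counting and the redundancy-aware per-protein rate statistic.

For a protein encoded by n genes with per-gene mutation counts m_i and CDS
lengths c_i (bp), the observed per-bp mutation rate pools the family:

    r = (sum_i m_i) / (sum_i c_i)

Only the nine consequence classes entering burden analyses are counted
(missense, silent, nonsense, nonstop, frameshift insertion/deletion, splice
site, splice region, translation start site); everything else is excluded.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    COUNTED_CLASSES,
    GeneModel,
    GeneMutationCount,
    ProteinGroup,
    ProteinRate,
    VariantRecord,
    build_protein_groups,
    registry_index,
)

logger = logging.getLogger(__name__)

PAN_CANCER = "pan-cancer"


def deduplicate(variants: Iterable[VariantRecord]) -> tuple[list[VariantRecord], int]:
    """Drop exact (patient, chrom, pos, alt) duplicate calls, keeping first."""
    seen: set[tuple[str, str, int, str]] = set()
    kept: list[VariantRecord] = []
    removed = 0
    for v in variants:
        key = (v.patient_id, v.chrom, v.pos, v.alt_allele)
        if key in seen:
            removed += 1
            continue
        seen.add(key)
        kept.append(v)
    if removed:
        logger.info("deduplicated %d exact duplicate calls", removed)
    return kept, removed


def eligible_cancer_types(
    clinical: Mapping[str, str], min_patients: int = 10
) -> set[str]:
    """Cancer types with at least ``min_patients`` patients."""
    counts: dict[str, int] = {}
    for ct in clinical.values():
        counts[ct] = counts.get(ct, 0) + 1
    return {ct for ct, n in counts.items() if n >= min_patients}


def count_mutations(
    variants: Sequence[VariantRecord],
    registry: Sequence[GeneModel],
    cancer_type: str | None = None,
) -> list[GeneMutationCount]:
    """Per-gene counted-class mutation totals and patients-mutated counts.

    ``cancer_type=None`` gives the pan-cancer tally. Records in genes absent
    from the registry are skipped under a warning bucket. Exact duplicate
    calls are removed first.
    """
    index = registry_index(registry)
    variants, _ = deduplicate(variants)
    m: dict[str, int] = {g: 0 for g in index}
    patients: dict[str, set[str]] = {g: set() for g in index}
    unknown = 0
    for v in variants:
        if cancer_type is not None and v.cancer_type != cancer_type:
            continue
        if v.classification not in COUNTED_CLASSES:
            continue
        if v.gene_symbol not in index:
            unknown += 1
            continue
        m[v.gene_symbol] += 1
        patients[v.gene_symbol].add(v.patient_id)
    if unknown:
        logger.warning("%d counted-class records in genes absent from registry",
                       unknown)
    label = cancer_type if cancer_type is not None else PAN_CANCER
    return [
        GeneMutationCount(gene_symbol=g, cancer_type=label, m=m[g],
                          patients_mutated=len(patients[g]))
        for g in index
    ]


def protein_rate(
    group: ProteinGroup, counts: Sequence[GeneMutationCount]
) -> ProteinRate:
    """Pooled rate r = (sum m_i)/(sum c_i) over the group's member genes."""
    by_gene = {c.gene_symbol: c for c in counts}
    m_total = sum(by_gene[g.gene_symbol].m if g.gene_symbol in by_gene else 0
                  for g in group.member_genes)
    c_total = group.total_cds_length
    if c_total <= 0:
        raise ValueError(f"group {group.protein_accession} has zero total CDS length")
    cancer_types = {c.cancer_type for c in counts} or {PAN_CANCER}
    return ProteinRate(
        protein_accession=group.protein_accession,
        cancer_type=cancer_types.pop() if len(cancer_types) == 1 else PAN_CANCER,
        m_total=m_total,
        c_total=c_total,
        r=m_total / c_total,
    )


def protein_rates_table(
    variants: Sequence[VariantRecord],
    registry: Sequence[GeneModel],
    clinical: Mapping[str, str] | None = None,
    min_patients: int = 10,
) -> pd.DataFrame:
    """Per-protein rates, pan-cancer plus each eligible cancer type.

    Cancer types with fewer than ``min_patients`` patients are reported only
    through the pan-cancer rows. Columns: protein_accession, cancer_type,
    m_total, c_total, r, is_histone, family.
    """
    groups = build_protein_groups(registry)
    cancer_types: list[str | None] = [None]
    if clinical is not None:
        cancer_types += sorted(eligible_cancer_types(clinical, min_patients))
    rows = []
    for ct in cancer_types:
        counts = count_mutations(variants, registry, cancer_type=ct)
        for group in groups:
            rate = protein_rate(group, counts)
            rows.append(
                {
                    "protein_accession": group.protein_accession,
                    "cancer_type": ct if ct is not None else PAN_CANCER,
                    "m_total": rate.m_total,
                    "c_total": rate.c_total,
                    "r": rate.r,
                    "is_histone": group.is_histone,
                    "family": group.family.value,
                }
            )
    return pd.DataFrame(rows)


def gene_rates(
    variants: Sequence[VariantRecord],
    registry: Sequence[GeneModel],
) -> dict[str, float]:
    """Pan-cancer per-gene rate m_i / c_i (covariate analyses operate here)."""
    counts = {c.gene_symbol: c.m for c in count_mutations(variants, registry)}
    return {g.gene_symbol: counts[g.gene_symbol] / g.cds_length for g in registry}
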