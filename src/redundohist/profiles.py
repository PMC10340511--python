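"""Cohort partitioning and SBS96 mutational-profile construction.

Patients split into those with at least one histone-gene mutation
(patient_set1) and the rest (patient_set2); mutations split into histone
calls of set1 (gene_group1), non-histone calls of set1 (gene_group2) and all
calls of set2 (gene_group3). Profiles count single-nucleotide substitutions
per pyrimidine-centred trinucleotide channel; purine-reference variants are
reverse-complemented, indels and MNVs are skipped with a logged count.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping, Sequence

import numpy as np

from . import sbs96
from .model import CohortPartition, GeneModel, MutationalProfile, VariantRecord

logger = logging.getLogger(__name__)


def partition_cohort(
    variants: Sequence[VariantRecord],
    registry: Sequence[GeneModel],
) -> CohortPartition:
    """Split patients and mutations by histone-mutation status.

    Every input mutation lands in exactly one gene group; the patient sets
    are disjoint. Genes absent from the registry are treated as non-histone.
    """
    histone_genes = {g.gene_symbol for g in registry if g.is_histone}
    all_patients = {v.patient_id for v in variants}
    set1 = {v.patient_id for v in variants if v.gene_symbol in histone_genes}
    set2 = all_patients - set1
    group1 = tuple(v for v in variants
                   if v.patient_id in set1 and v.gene_symbol in histone_genes)
    group2 = tuple(v for v in variants
                   if v.patient_id in set1 and v.gene_symbol not in histone_genes)
    group3 = tuple(v for v in variants if v.patient_id in set2)
    return CohortPartition(
        patient_set1=frozenset(set1),
        patient_set2=frozenset(set2),
        gene_group1=group1,
        gene_group2=group2,
        gene_group3=group3,
    )


ContextSource = Callable[[VariantRecord], str | None]


def reference_context_source(
    reference: Mapping[str, str] | Mapping[str, Sequence[str]],
    locations: Mapping[str, int] | None = None,
) -> ContextSource:
    """Context lookup from per-gene CDS strings (or chrom-keyed sequences).

    With ``locations`` (gene -> genomic start) the record's 1-based position
    is mapped back into its gene's CDS; without it, ``reference`` is indexed
    by chromosome directly at the genomic coordinate.
    """

    def lookup(v: VariantRecord) -> str | None:
        if locations is not None:
            seq = reference.get(v.gene_symbol)
            if seq is None:
                return None
            offset = v.pos - locations[v.gene_symbol]
        else:
            seq = reference.get(v.chrom)
            if seq is None:
                return None
            offset = v.pos - 1
        if offset < 1 or offset > len(seq) - 2:
            return None
        ctx = seq[offset - 1:offset + 2]
        return str(ctx).upper()

    return lookup


def build_profile(
    variants: Sequence[VariantRecord],
    context_source: ContextSource | None = None,
    label: str = "",
) -> tuple[MutationalProfile, int]:
    """SBS96 channel counts for a variant subset; returns (profile, n_skipped).

    Contexts come from each record's context field, falling back to
    ``context_source``; a contributing SNV with no context available at all
    is a hard error listing the offending variants. Non-SNVs are skipped and
    counted. Channel sums always equal the number of contributing SNVs.
    """
    counts = np.zeros(96, dtype=np.int64)
    skipped = 0
    missing: list[str] = []
    for v in variants:
        if not v.is_snv:
            skipped += 1
            continue
        context = v.context
        if context is None and context_source is not None:
            context = context_source(v)
        if context is None:
            missing.append(f"{v.gene_symbol}:{v.chrom}:{v.pos}")
            continue
        counts[sbs96.channel_of(v.ref_allele, v.alt_allele, context)] += 1
    if missing:
        raise ValueError(
            f"no trinucleotide context for {len(missing)} SNVs "
            f"(e.g. {missing[:5]}); supply a reference context source"
        )
    if skipped:
        logger.info("profile %s: skipped %d non-SNV records", label or "<unnamed>",
                    skipped)
    return MutationalProfile(counts=counts, label=label), skipped
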