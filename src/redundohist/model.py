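"""Shared data model: variants, genes, protein groups, profiles, catalogs.

Coordinates are 1-based inclusive (MAF convention). Trinucleotide contexts
are always carried on the reference strand; pyrimidine collapsing happens in
profile construction, not at I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from . import sbs96


class VariantClass(str, Enum):
    MISSENSE = "missense"
    SILENT = "silent"
    NONSENSE = "nonsense"
    NONSTOP = "nonstop"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    SPLICE_SITE = "splice_site"
    SPLICE_REGION = "splice_region"
    TRANSLATION_START_SITE = "translation_start_site"
    OTHER = "other"


#: The nine consequence classes that enter mutation-burden counting.
COUNTED_CLASSES: frozenset[VariantClass] = frozenset(
    c for c in VariantClass if c is not VariantClass.OTHER
)


class HistoneFamily(str, Enum):
    H1 = "H1"
    H2A = "H2A"
    H2B = "H2B"
    H3 = "H3"
    H4 = "H4"
    NON_HISTONE = "non_histone"


HISTONE_FAMILIES: tuple[HistoneFamily, ...] = (
    HistoneFamily.H1,
    HistoneFamily.H2A,
    HistoneFamily.H2B,
    HistoneFamily.H3,
    HistoneFamily.H4,
)


class HistoneClass(str, Enum):
    CANONICAL = "canonical"
    VARIANT = "variant"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One somatic mutation call from a MAF-style table."""

    patient_id: str
    gene_symbol: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    classification: VariantClass
    cancer_type: str = ""
    context: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt ({self.ref_allele}) at {self.chrom}:{self.pos}")
        if self.context is not None:
            if len(self.context) != 3:
                raise ValueError(f"context must be a 3-mer, got {self.context!r}")
            if self.is_snv and self.context[1].upper() != self.ref_allele.upper():
                raise ValueError(
                    f"context {self.context} middle base != ref {self.ref_allele} "
                    f"at {self.chrom}:{self.pos}"
                )

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele.upper() in "ACGT"
            and self.alt_allele.upper() in "ACGT"
        )


@dataclass(frozen=True, slots=True)
class GeneModel:
    """One protein-coding gene and its place in the redundancy map."""

    gene_symbol: str
    protein_accession: str
    cds_length: int
    family: HistoneFamily = HistoneFamily.NON_HISTONE
    histone_class: HistoneClass = HistoneClass.NOT_APPLICABLE
    chrom: str = ""

    def __post_init__(self) -> None:
        if self.cds_length <= 0:
            raise ValueError(f"cds_length must be > 0 for {self.gene_symbol}")

    @property
    def is_histone(self) -> bool:
        return self.family is not HistoneFamily.NON_HISTONE


@dataclass(frozen=True)
class ProteinGroup:
    """All genes encoding one protein — the aggregation unit of the rate statistic."""

    protein_accession: str
    member_genes: tuple[GeneModel, ...]

    def __post_init__(self) -> None:
        if not self.member_genes:
            raise ValueError("a protein group needs at least one member gene")
        if any(g.protein_accession != self.protein_accession for g in self.member_genes):
            raise ValueError(f"mixed accessions in group {self.protein_accession}")

    @property
    def n(self) -> int:
        return len(self.member_genes)

    @property
    def total_cds_length(self) -> int:
        return sum(g.cds_length for g in self.member_genes)

    @property
    def is_histone(self) -> bool:
        return any(g.is_histone for g in self.member_genes)

    @property
    def family(self) -> HistoneFamily:
        return self.member_genes[0].family


@dataclass
class SignatureCatalog:
    """A 96 x K matrix of mutational-signature channel probabilities."""

    matrix: np.ndarray
    signature_names: list[str]
    channel_order: tuple[str, ...] = sbs96.CHANNELS
    etiology_groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.signature_names)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match 96 x "
                f"{len(self.signature_names)} signatures"
            )
        if (self.matrix < 0).any():
            raise ValueError("signature matrix has negative entries")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            bad = [self.signature_names[i] for i in np.nonzero(np.abs(sums - 1) > 1e-3)[0]]
            raise ValueError(f"signature columns do not sum to 1: {bad}")
        self.matrix = self.matrix / sums  # renormalize residual drift
        if tuple(self.channel_order) != sbs96.CHANNELS:
            order = [list(self.channel_order).index(c) for c in sbs96.CHANNELS]
            self.matrix = self.matrix[order]
            self.channel_order = sbs96.CHANNELS

    @property
    def n_signatures(self) -> int:
        return len(self.signature_names)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.signature_names.index(name)]

    def subset(self, names: Sequence[str]) -> "SignatureCatalog":
        idx = [self.signature_names.index(n) for n in names]
        return SignatureCatalog(
            matrix=self.matrix[:, idx],
            signature_names=list(names),
            etiology_groups=self.etiology_groups,
        )


@dataclass
class MutationalProfile:
    """96-channel single-base-substitution count vector in canonical order."""

    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96,):
            raise ValueError(f"profile must have 96 channels, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative channel counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def normalized(self) -> np.ndarray:
        t = self.counts.sum()
        if t == 0:
            raise ValueError(f"profile {self.label!r} is empty")
        return self.counts / t


@dataclass
class DecompositionResult:
    """Signature exposures (percent of mutations per process) with optional bootstrap CIs."""

    exposures: dict[str, float]
    log_likelihood: float
    n_mutations: int
    bootstrap_mean: dict[str, float] | None = None
    ci_low: dict[str, float] | None = None
    ci_high: dict[str, float] | None = None
    active: frozenset[str] = frozenset()
    merged: dict[str, float] | None = None

    def __post_init__(self) -> None:
        total = sum(self.exposures.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"exposures sum to {total}, expected 100")


@dataclass(frozen=True)
class CohortPartition:
    """Patient/mutation partition used for signature analysis.

    ``patient_set1`` holds patients with at least one histone mutation;
    ``patient_set2`` the rest. Mutations of set1 split into histone-gene
    (``gene_group1``) and non-histone-gene (``gene_group2``) calls; all
    mutations of set2 form ``gene_group3``.
    """

    patient_set1: frozenset[str]
    patient_set2: frozenset[str]
    gene_group1: tuple[VariantRecord, ...]
    gene_group2: tuple[VariantRecord, ...]
    gene_group3: tuple[VariantRecord, ...]


@dataclass(frozen=True)
class GeneMutationCount:
    gene_symbol: str
    cancer_type: str
    m: int
    patients_mutated: int

    def __post_init__(self) -> None:
        if self.m < 0 or self.patients_mutated < 0:
            raise ValueError("negative counts")
        if self.patients_mutated > self.m:
            raise ValueError("patients_mutated cannot exceed mutation count")


@dataclass(frozen=True)
class ProteinRate:
    """Pooled per-bp observed mutation rate r = (sum m_i) / (sum c_i)."""

    protein_accession: str
    cancer_type: str
    m_total: int
    c_total: int
    r: float

    def __post_init__(self) -> None:
        if self.c_total <= 0:
            raise ValueError("c_total must be positive")


def registry_index(registry: Sequence[GeneModel]) -> Mapping[str, GeneModel]:
    """Gene symbol -> GeneModel, rejecting duplicates."""
    index: dict[str, GeneModel] = {}
    for gene in registry:
        if gene.gene_symbol in index:
            raise ValueError(f"duplicate gene symbol {gene.gene_symbol!r} in registry")
        index[gene.gene_symbol] = gene
    return index


def build_protein_groups(registry: Sequence[GeneModel]) -> list[ProteinGroup]:
    """Partition a registry into protein groups (genes sharing an accession).

    Every gene lands in exactly one group; group sizes sum to the registry size.
    """
    if not registry:
        raise ValueError("registry is empty")
    registry_index(registry)  # duplicate check
    by_accession: dict[str, list[GeneModel]] = {}
    for gene in registry:
        by_accession.setdefault(gene.protein_accession, []).append(gene)
    return [
        ProteinGroup(protein_accession=acc, member_genes=tuple(genes))
        for acc, genes in by_accession.items()
    ]
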