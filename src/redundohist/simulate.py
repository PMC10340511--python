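"""Synthetic multi-cancer cohorts with known ground truth.

The generator emulates the statistical structure of a pan-cancer WES cohort
over a registry that contains redundant histone-like gene families (up to 11
genes per protein, clustered loci) next to ordinary single-copy genes:

* per-patient mutation burdens are negative-binomial (heavy-tailed);
* a mutation picks a gene with probability proportional to CDS length times
  a per-gene rate multiplier (the designed-in "driver" dial);
* its SBS96 channel is drawn from a configured mixture of signature catalog
  columns, restricted to the channels for which the gene's simulated CDS
  actually contains a matching trinucleotide site (either strand,
  pyrimidine-collapsed) — equivalent to rejection sampling but vectorized;
* the genomic position is uniform over the matching sites;
* consequences are assigned silent:missense at a fixed 1:3 ratio with small
  fixed probabilities for the remaining classes.

Everything is driven by one integer seed; re-runs are byte-identical.
Ground truth records the true exposures, the availability-corrected
(effective) channel mixtures, per-gene multipliers and realized counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import sbs96
from .model import (
    GeneModel,
    HistoneClass,
    HistoneFamily,
    SignatureCatalog,
    VariantClass,
    VariantRecord,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Consequence-class sampling distribution. The single-nucleotide bulk is
#: split silent:missense = 1:3; the remaining classes get small fixed masses.
CLASS_PROBS: dict[VariantClass, float] = {
    VariantClass.MISSENSE: 0.6675,
    VariantClass.SILENT: 0.2225,
    VariantClass.NONSENSE: 0.02,
    VariantClass.NONSTOP: 0.005,
    VariantClass.SPLICE_SITE: 0.01,
    VariantClass.SPLICE_REGION: 0.01,
    VariantClass.TRANSLATION_START_SITE: 0.005,
    VariantClass.FRAMESHIFT_INSERTION: 0.02,
    VariantClass.FRAMESHIFT_DELETION: 0.02,
    VariantClass.OTHER: 0.02,
}

_INDEL_CLASSES = {VariantClass.FRAMESHIFT_INSERTION, VariantClass.FRAMESHIFT_DELETION}


@dataclass(frozen=True)
class GeneFamilySpec:
    """One protein and the redundant genes that encode it."""

    protein_accession: str
    n_genes: int
    cds_length: int
    family: HistoneFamily = HistoneFamily.NON_HISTONE
    histone_class: HistoneClass = HistoneClass.NOT_APPLICABLE
    chrom: str = "1"
    symbol_prefix: str = ""


def make_registry(spec: Sequence[GeneFamilySpec]) -> list[GeneModel]:
    """Expand family specs into a flat gene registry."""
    registry: list[GeneModel] = []
    for fam in spec:
        prefix = fam.symbol_prefix or fam.protein_accession
        for i in range(1, fam.n_genes + 1):
            symbol = f"{prefix}{i}" if fam.n_genes > 1 or not fam.symbol_prefix else prefix
            registry.append(
                GeneModel(
                    gene_symbol=symbol,
                    protein_accession=fam.protein_accession,
                    cds_length=fam.cds_length,
                    family=fam.family,
                    histone_class=fam.histone_class,
                    chrom=fam.chrom,
                )
            )
    return registry


def default_registry_spec(n_background: int = 50) -> list[GeneFamilySpec]:
    """A histone-like registry: redundant clustered families plus background genes.

    Families mirror the real redundancy structure (an 11-gene H4 protein, a
    10-gene H3.1, smaller H2A/H2B/H1 groups, dispersed variant histones) and
    a POLE-like replicative polymerase gene for co-occurrence analyses.
    Background genes are single-copy with varied CDS lengths.
    """
    spec = [
        GeneFamilySpec("P62805", 11, 312, HistoneFamily.H4, HistoneClass.CANONICAL, "6", "H4C"),
        GeneFamilySpec("P68431", 10, 411, HistoneFamily.H3, HistoneClass.CANONICAL, "6", "H3C"),
        GeneFamilySpec("Q71DI3", 3, 411, HistoneFamily.H3, HistoneClass.CANONICAL, "1", "H3-2C"),
        GeneFamilySpec("P62807", 5, 381, HistoneFamily.H2B, HistoneClass.CANONICAL, "6", "H2BC"),
        GeneFamilySpec("P0C0S8", 4, 393, HistoneFamily.H2A, HistoneClass.CANONICAL, "6", "H2AC"),
        GeneFamilySpec("P10412", 1, 660, HistoneFamily.H1, HistoneClass.CANONICAL, "6", "H1-4"),
        GeneFamilySpec("P16403", 1, 639, HistoneFamily.H1, HistoneClass.CANONICAL, "6", "H1-2"),
        GeneFamilySpec("Q8IZA3", 1, 600, HistoneFamily.H1, HistoneClass.VARIANT, "3", "H1-8"),
        GeneFamilySpec("P84243", 2, 411, HistoneFamily.H3, HistoneClass.VARIANT, "1", "H3-3"),
        GeneFamilySpec("P0C0S5", 1, 387, HistoneFamily.H2A, HistoneClass.VARIANT, "4", "H2AZ"),
        GeneFamilySpec("Q07864", 1, 6858, HistoneFamily.NON_HISTONE,
                       HistoneClass.NOT_APPLICABLE, "12", "POLE"),
    ]
    chroms = [str(c) for c in (1, 2, 3, 5, 7, 8, 9, 10, 11, 12)]
    for i in range(n_background):
        length = 900 + 137 * (i % 17) + 60 * (i % 7)
        spec.append(
            GeneFamilySpec(
                protein_accession=f"BG{i:04d}",
                n_genes=1,
                cds_length=length,
                chrom=chroms[i % len(chroms)],
                symbol_prefix=f"GENE{i:03d}",
            )
        )
    return spec


def gene_locations(registry: Sequence[GeneModel],
                   spacing: int = 100_000) -> dict[str, int]:
    """Deterministic 1-based genomic start coordinate per gene (clustered by chrom)."""
    starts: dict[str, int] = {}
    per_chrom: dict[str, int] = {}
    for gene in registry:
        k = per_chrom.get(gene.chrom, 0)
        starts[gene.gene_symbol] = 1 + k * spacing
        per_chrom[gene.chrom] = k + 1
    return starts


def simulate_reference(
    registry: Sequence[GeneModel],
    seed: int,
    gc_content: float = 0.5,
) -> dict[str, str]:
    """Random CDS nucleotide strings per gene. Deterministic given seed.

    Per-gene streams are keyed by (seed, gene index) so the sequence of one
    gene does not depend on how many genes precede it being resampled.
    """
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must lie in (0, 1)")
    reference: dict[str, str] = {}
    p = np.array([(1 - gc_content) / 2, gc_content / 2, gc_content / 2,
                  (1 - gc_content) / 2])
    for idx, gene in enumerate(registry):
        if gene.cds_length < 10:
            raise ValueError(f"cds_length < 10 for {gene.gene_symbol}")
        rng = np.random.default_rng([seed, idx])
        draws = rng.choice(4, size=gene.cds_length, p=p)
        reference[gene.gene_symbol] = "".join("ACGT"[b] for b in draws)
    return reference


def _site_index(seq: str) -> dict[str, np.ndarray]:
    """Pyrimidine-collapsed trinucleotide -> 0-based interior centre offsets."""
    sites: dict[str, list[int]] = {}
    for o in range(1, len(seq) - 1):
        tri = seq[o - 1:o + 2]
        key = tri if tri[1] in "CT" else sbs96.revcomp(tri)
        sites.setdefault(key, []).append(o)
    return {k: np.asarray(v, dtype=np.int64) for k, v in sites.items()}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    seed: int
    n_patients: int = 500
    cancer_type_weights: dict[str, float] = field(
        default_factory=lambda: {
            "squamous cell carcinoma": 0.30,
            "infiltrating duct carcinoma": 0.25,
            "adenocarcinoma": 0.20,
            "hepatocellular carcinoma": 0.15,
            "multiple myeloma": 0.10,
        }
    )
    registry_spec: list[GeneFamilySpec] = field(default_factory=default_registry_spec)
    per_gene_rate_multiplier: dict[str, float] = field(default_factory=dict)
    burden_mean: float = 50.0
    burden_dispersion: float = 2.0
    #: signature weights per gene-group label ("histone" / "non_histone" or "all")
    signature_mixture: dict[str, dict[str, float]] = field(default_factory=dict)
    hypermutator_fraction: float = 0.0
    hypermutator_signature: str | None = None
    hypermutator_signature_weight: float = 0.5
    hypermutator_burden_factor: float = 10.0
    gc_content: float = 0.5

    def __post_init__(self) -> None:
        total = sum(self.cancer_type_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cancer type weights sum to {total}, expected 1")
        if any(m <= 0 for m in self.per_gene_rate_multiplier.values()):
            raise ValueError("rate multipliers must be positive")
        for label, mix in self.signature_mixture.items():
            s = sum(mix.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"signature mixture {label!r} sums to {s}, expected 1")


@dataclass
class SimulationResult:
    variants: list[VariantRecord]
    clinical: dict[str, str]
    registry: list[GeneModel]
    reference: dict[str, str]
    ground_truth: dict


def _mixture_vector(mix: Mapping[str, float], catalog: SignatureCatalog) -> np.ndarray:
    v = np.zeros(96)
    for name, w in mix.items():
        v += w * catalog.column(name)
    return v


def _group_label(gene: GeneModel) -> str:
    return "histone" if gene.is_histone else "non_histone"


def simulate_cohort(
    config: SimulationConfig,
    catalog: SignatureCatalog,
    registry: list[GeneModel] | None = None,
    reference: dict[str, str] | None = None,
) -> SimulationResult:
    """Draw a full synthetic cohort; see the module docstring for the model.

    Raises if any gene has no eligible site for every positive-probability
    channel of its mixture (cannot place a single mutation).
    """
    rng = np.random.default_rng(config.seed)
    if registry is None:
        registry = make_registry(config.registry_spec)
    if reference is None:
        reference = simulate_reference(registry, seed=config.seed,
                                       gc_content=config.gc_content)
    mixtures = dict(config.signature_mixture)
    if not mixtures:
        mixtures = {"all": {catalog.signature_names[0]: 1.0}}

    genes = list(registry)
    n_genes = len(genes)
    starts = gene_locations(genes)
    site_indices = [_site_index(reference[g.gene_symbol]) for g in genes]

    # gene selection probabilities: CDS length x rate multiplier
    multipliers = np.array(
        [config.per_gene_rate_multiplier.get(g.gene_symbol, 1.0) for g in genes]
    )
    weights = np.array([g.cds_length for g in genes], dtype=float) * multipliers
    p_gene = weights / weights.sum()

    # per-gene availability-masked channel distributions, normal + hypermutator
    tri_of_channel = [sbs96.pyrimidine_context(c) for c in range(96)]

    def effective(gene_i: int, mix_vec: np.ndarray) -> np.ndarray:
        avail = np.array(
            [1.0 if tri_of_channel[c] in site_indices[gene_i] else 0.0
             for c in range(96)]
        )
        eff = mix_vec * avail
        s = eff.sum()
        if s <= 0:
            raise ValueError(
                f"gene {genes[gene_i].gene_symbol} has no eligible site for any "
                "positive-probability channel"
            )
        return eff / s

    base_mix = {}
    for label in ("histone", "non_histone"):
        mix = mixtures.get(label, mixtures.get("all"))
        if mix is None:
            raise ValueError(f"no signature mixture for gene group {label!r}")
        base_mix[label] = _mixture_vector(mix, catalog)
    hyper_mix = None
    if config.hypermutator_signature is not None:
        w = config.hypermutator_signature_weight
        extra = catalog.column(config.hypermutator_signature)
        hyper_mix = {
            label: (1 - w) * vec + w * extra for label, vec in base_mix.items()
        }

    eff_normal = np.stack([effective(i, base_mix[_group_label(g)])
                           for i, g in enumerate(genes)])
    eff_hyper = (
        np.stack([effective(i, hyper_mix[_group_label(g)])
                  for i, g in enumerate(genes)])
        if hyper_mix is not None else eff_normal
    )

    # patients
    n = config.n_patients
    patient_ids = [f"P{i:05d}" for i in range(n)]
    ct_names = list(config.cancer_type_weights)
    ct_probs = np.array([config.cancer_type_weights[c] for c in ct_names])
    cancer_types = [ct_names[i] for i in rng.choice(len(ct_names), size=n, p=ct_probs)]
    hyper_flags = rng.random(n) < config.hypermutator_fraction

    mean = np.where(hyper_flags,
                    config.burden_mean * config.hypermutator_burden_factor,
                    config.burden_mean)
    k = config.burden_dispersion
    burdens = rng.negative_binomial(k, k / (k + mean))
    total = int(burdens.sum())

    mut_patient = np.repeat(np.arange(n), burdens)
    gene_idx = rng.choice(n_genes, size=total, p=p_gene)

    # channel draw via inverse CDF against each mutation's effective distribution
    eff_rows = np.where(hyper_flags[mut_patient][:, None],
                        eff_hyper[gene_idx], eff_normal[gene_idx])
    u = rng.random(total)
    channels = (u[:, None] > np.cumsum(eff_rows, axis=1)).sum(axis=1)
    channels = np.minimum(channels, 95)

    cls_list = list(CLASS_PROBS)
    cls_probs = np.array([CLASS_PROBS[c] for c in cls_list])
    cls_draw = rng.choice(len(cls_list), size=total, p=cls_probs)
    u_site = rng.random(total)
    ins_bases = rng.integers(0, 4, size=total)

    variants: list[VariantRecord] = []
    gene_counts = np.zeros(n_genes, dtype=np.int64)
    for j in range(total):
        gi = int(gene_idx[j])
        gene = genes[gi]
        seq = reference[gene.gene_symbol]
        c = int(channels[j])
        tri = tri_of_channel[c]
        sites = site_indices[gi][tri]
        o = int(sites[int(u_site[j] * len(sites)) % len(sites)])
        context = seq[o - 1:o + 2]
        _f, pref, palt, _t = sbs96.parse_channel(sbs96.CHANNELS[c])
        if seq[o] == pref:
            ref, alt = pref, palt
        else:  # purine strand: complement the channel alleles
            ref, alt = _COMP[pref], _COMP[palt]
        cls = cls_list[cls_draw[j]]
        ctx: str | None = context
        if cls is VariantClass.FRAMESHIFT_DELETION:
            alt, ctx = "-", None
        elif cls is VariantClass.FRAMESHIFT_INSERTION:
            ref, alt, ctx = "-", "ACGT"[int(ins_bases[j])], None
        pid = int(mut_patient[j])
        variants.append(
            VariantRecord(
                patient_id=patient_ids[pid],
                gene_symbol=gene.gene_symbol,
                chrom=gene.chrom,
                pos=starts[gene.gene_symbol] + o,
                ref_allele=ref,
                alt_allele=alt,
                classification=cls,
                cancer_type=cancer_types[pid],
                context=ctx,
            )
        )
        gene_counts[gi] += 1

    # availability-corrected (effective) group mixtures: gene-weighted average
    effective_mixture = {}
    for label in ("histone", "non_histone"):
        members = [i for i, g in enumerate(genes) if _group_label(g) == label]
        if not members:
            continue
        pw = p_gene[members] / p_gene[members].sum()
        effective_mixture[label] = (pw[:, None] * eff_normal[members]).sum(axis=0)

    ground_truth = {
        "signature_mixture": {label: dict(mixtures.get(label, mixtures.get("all")))
                              for label in ("histone", "non_histone")},
        "effective_mixture": effective_mixture,
        "per_gene_multiplier": {g.gene_symbol: float(multipliers[i])
                                for i, g in enumerate(genes)},
        "per_gene_selection_prob": {g.gene_symbol: float(p_gene[i])
                                    for i, g in enumerate(genes)},
        "per_gene_counts": {g.gene_symbol: int(gene_counts[i])
                            for i, g in enumerate(genes)},
        "per_patient_burden": {patient_ids[i]: int(burdens[i]) for i in range(n)},
        "hypermutators": [patient_ids[i] for i in range(n) if hyper_flags[i]],
        "n_mutations": total,
    }
    clinical = dict(zip(patient_ids, cancer_types))
    return SimulationResult(variants, clinical, genes, reference, ground_truth)


def solve_joint_probability(p_query: float, p_histone: float,
                            odds_ratio: float) -> float:
    """P(query & histone) for given margins and odds ratio (Plackett coupling)."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if abs(odds_ratio - 1.0) < 1e-12:
        return p_query * p_histone
    s = 1 + (p_query + p_histone) * (odds_ratio - 1)
    disc = s * s - 4 * odds_ratio * (odds_ratio - 1) * p_query * p_histone
    return (s - np.sqrt(disc)) / (2 * (odds_ratio - 1))


def simulate_cooccurrence_cohort(
    n_patients: int,
    odds_ratio: float,
    seed: int,
    p_query: float = 0.15,
    p_histone: float = 0.25,
    query_gene: str = "POLE",
    registry: list[GeneModel] | None = None,
    reference: dict[str, str] | None = None,
) -> SimulationResult:
    """Cohort with a designed-in query-gene/histone-mutation association.

    Patient-level mutation indicators are drawn from the 2x2 joint
    distribution with the requested margins and odds ratio; each positive
    indicator materializes as one missense call at a random CDS site, and
    every patient receives one background non-histone call so all patients
    are observed.
    """
    rng = np.random.default_rng(seed)
    if registry is None:
        registry = make_registry(default_registry_spec())
    if reference is None:
        reference = simulate_reference(registry, seed=seed)
    starts = gene_locations(registry)
    histone_genes = [g for g in registry if g.is_histone]
    background = [g for g in registry
                  if not g.is_histone and g.gene_symbol != query_gene]
    query = next(g for g in registry if g.gene_symbol == query_gene)

    a = solve_joint_probability(p_query, p_histone, odds_ratio)
    cells = np.array([a, p_query - a, p_histone - a,
                      1 - p_query - p_histone + a])
    if (cells < -1e-12).any():
        raise ValueError("margins incompatible with requested odds ratio")
    cells = np.clip(cells, 0, None)
    cells /= cells.sum()
    draw = rng.choice(4, size=n_patients, p=cells)
    q_flag = (draw == 0) | (draw == 1)
    h_flag = (draw == 0) | (draw == 2)

    def random_snv(gene: GeneModel, pid: str, ct: str) -> VariantRecord:
        seq = reference[gene.gene_symbol]
        o = int(rng.integers(1, len(seq) - 1))
        ref = seq[o]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return VariantRecord(
            patient_id=pid, gene_symbol=gene.gene_symbol, chrom=gene.chrom,
            pos=starts[gene.gene_symbol] + o, ref_allele=ref, alt_allele=str(alt),
            classification=VariantClass.MISSENSE, cancer_type=ct,
            context=seq[o - 1:o + 2],
        )

    variants: list[VariantRecord] = []
    clinical: dict[str, str] = {}
    ct = "pan-cancer"
    for i in range(n_patients):
        pid = f"P{i:05d}"
        clinical[pid] = ct
        if q_flag[i]:
            variants.append(random_snv(query, pid, ct))
        if h_flag[i]:
            hg = histone_genes[int(rng.integers(len(histone_genes)))]
            variants.append(random_snv(hg, pid, ct))
        bg = background[int(rng.integers(len(background)))]
        variants.append(random_snv(bg, pid, ct))

    a_n = int((q_flag & h_flag).sum())
    b_n = int((q_flag & ~h_flag).sum())
    c_n = int((~q_flag & h_flag).sum())
    d_n = int((~q_flag & ~h_flag).sum())
    ground_truth = {
        "odds_ratio": odds_ratio,
        "joint_cells": cells.tolist(),
        "realized_table": [[a_n, b_n], [c_n, d_n]],
        "query_gene": query_gene,
    }
    return SimulationResult(variants, clinical, list(registry), reference,
                            ground_truth)


def synthetic_signature_catalog(
    n_signatures: int = 3,
    seed: int = 0,
    block_mass: float = 0.9,
    names: Sequence[str] | None = None,
) -> SignatureCatalog:
    """Well-separated synthetic SBS96 signatures.

    Channel set is split into ``n_signatures`` contiguous blocks; signature k
    places ``block_mass`` of its probability (Dirichlet-distributed) on its
    own block and the remainder spread over the others, so columns are nearly
    orthogonal and refitting is identifiable.
    """
    if not 1 <= n_signatures <= 96:
        raise ValueError("need between 1 and 96 signatures")
    rng = np.random.default_rng(seed)
    edges = np.linspace(0, 96, n_signatures + 1).astype(int)
    matrix = np.zeros((96, n_signatures))
    for k in range(n_signatures):
        own = np.arange(edges[k], edges[k + 1])
        rest = np.setdiff1d(np.arange(96), own)
        matrix[own, k] = block_mass * rng.dirichlet(np.ones(len(own)))
        matrix[rest, k] = (1 - block_mass) * rng.dirichlet(np.ones(len(rest)))
    if names is None:
        names = [f"SYN{k + 1}" for k in range(n_signatures)]
    return SignatureCatalog(matrix=matrix, signature_names=list(names))
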