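"""End-to-end orchestration: one YAML config, per-stage outputs, a manifest.

Stages (any subset, default all): rates, comparisons, family, homogeneity,
signatures, association, covariates. One top-level seed is fanned out to
per-stage seeds by hashing the stage name, so stages can be rerun
independently and reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__, io, profiles, signatures
from .association import cooccurrence_test, covariate_correlation
from .compare import family_comparison, histone_vs_group_comparison
from .homogeneity import homogeneity_scan
from .model import build_protein_groups
from .rates import count_mutations, gene_rates, protein_rates_table

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("rates", "comparisons", "family", "homogeneity",
                "signatures", "association", "covariates")


@dataclass
class PipelineConfig:
    maf: str
    registry: str
    clinical: str | None = None
    catalog: str | None = None
    covariates: str | None = None
    drivers: str | None = None
    driver_mutations: str | None = None
    query_genes: list[str] = field(default_factory=lambda: ["POLE"])
    min_patients_per_cancer_type: int = 10
    min_mutations_per_family: int = 10
    fdr: float = 0.05
    n_sim: int = 10_000
    n_boot: int = 100
    seed: int = 0
    include_flat: bool = False
    stages: list[str] = field(default_factory=lambda: list(KNOWN_STAGES))

    def __post_init__(self) -> None:
        for threshold in (self.min_patients_per_cancer_type,
                          self.min_mutations_per_family, self.n_sim, self.n_boot):
            if threshold <= 0:
                raise ValueError("thresholds and simulation sizes must be positive")
        unknown = set(self.stages) - set(KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the configured stages; returns the report directory.

    Each stage writes TSV/JSON under ``out_dir``; skipped analyses carry a
    machine-readable reason in the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clinical = io.read_clinical(config.clinical) if config.clinical else None
    variants = io.read_variants(config.maf, dialect="maf", clinical=clinical)
    registry = io.read_registry(config.registry)
    skips: list[dict] = []

    inputs = {"maf": config.maf, "registry": config.registry}
    for name in ("clinical", "catalog", "covariates", "drivers",
                 "driver_mutations"):
        if getattr(config, name):
            inputs[name] = getattr(config, name)

    rates_df = protein_rates_table(
        variants, registry, clinical=clinical,
        min_patients=config.min_patients_per_cancer_type,
    )

    if "rates" in config.stages:
        rates_df.to_csv(out / "protein_rates.tsv", sep="\t", index=False)

    if "comparisons" in config.stages:
        table = histone_vs_group_comparison(rates_df)
        table.to_csv(out / "histone_vs_nonhistone.tsv", sep="\t", index=False)
        if config.drivers:
            driver_symbols = set(io.read_driver_list(config.drivers))
            histone_genes = {g.gene_symbol for g in registry if g.is_histone}
            driver_symbols -= histone_genes  # histones removed from the driver set
            accessions = {
                g.protein_accession for g in registry
                if g.gene_symbol in driver_symbols
            }
            dtable = histone_vs_group_comparison(
                rates_df, comparison="drivers", driver_proteins=accessions,
            )
            dtable.to_csv(out / "histone_vs_drivers.tsv", sep="\t", index=False)

    if "family" in config.stages:
        totals = _family_mutation_totals(variants, registry, clinical,
                                         config.min_patients_per_cancer_type)
        table, skipped = family_comparison(
            rates_df, totals, min_mutations=config.min_mutations_per_family,
        )
        table.to_csv(out / "family_comparison.tsv", sep="\t", index=False)
        skips.extend({"stage": "family", **s} for s in skipped)

    if "homogeneity" in config.stages:
        table = homogeneity_scan(
            variants, registry, clinical=clinical,
            min_patients=config.min_patients_per_cancer_type,
            n_sim=config.n_sim, seed=stage_seed(config.seed, "homogeneity"),
        )
        table.to_csv(out / "homogeneity.tsv", sep="\t", index=False)

    if "signatures" in config.stages:
        if not config.catalog:
            skips.append({"stage": "signatures", "reason": "no catalog provided"})
        else:
            catalog = io.read_signature_catalog(
                config.catalog, etiology_groups=signatures.ETIOLOGY_GROUPS,
            )
            _signature_stage(variants, registry, catalog, config, out, skips)

    if "association" in config.stages:
        driver_pos = (io.read_driver_mutations(config.driver_mutations)
                      if config.driver_mutations else None)
        result = cooccurrence_test(
            variants, registry, query_genes=config.query_genes,
            patients=clinical.keys() if clinical else None,
            restrict_to_driver_positions=driver_pos,
        )
        (out / "cooccurrence.json").write_text(json.dumps({
            "table": result.table, "odds_ratio": result.odds_ratio,
            "p_one_sided": result.p_one_sided, "direction": result.direction,
            "haldane_corrected": result.haldane_corrected,
            "degenerate": result.degenerate,
        }, indent=2))

    if "covariates" in config.stages:
        if not config.covariates:
            skips.append({"stage": "covariates", "reason": "no covariate table"})
        else:
            cov = io.read_covariates(config.covariates)
            histone_rates = {
                g: r for g, r in gene_rates(variants, registry).items()
                if any(x.gene_symbol == g and x.is_histone for x in registry)
            }
            rows = [asdict(c) for c in covariate_correlation(histone_rates, cov)]
            pd.DataFrame(rows).to_csv(out / "covariate_correlations.tsv",
                                      sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": config.stages,
        "inputs": {name: {"path": str(p), "sha256_16": _checksum(p)}
                   for name, p in inputs.items()},
        "n_variants": len(variants),
        "n_genes": len(registry),
        "skipped": skips,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _family_mutation_totals(variants, registry, clinical, min_patients):
    from .rates import PAN_CANCER, eligible_cancer_types

    by_gene = {g.gene_symbol: g for g in registry}
    cts: list[str | None] = [None]
    if clinical is not None:
        cts += sorted(eligible_cancer_types(clinical, min_patients))
    rows = []
    for ct in cts:
        counts = count_mutations(variants, registry, cancer_type=ct)
        totals: dict[str, int] = {}
        for c in counts:
            fam = by_gene[c.gene_symbol].family.value
            totals[fam] = totals.get(fam, 0) + c.m
        label = ct if ct is not None else PAN_CANCER
        rows.extend({"cancer_type": label, "family": fam, "m_total": m}
                    for fam, m in totals.items())
    return pd.DataFrame(rows)


def _signature_stage(variants, registry, catalog, config, out: Path,
                     skips: list[dict]) -> None:
    partition = profiles.partition_cohort(variants, registry)
    groups = {
        "gene_group1": partition.gene_group1,
        "gene_group2": partition.gene_group2,
        "gene_group3": partition.gene_group3,
    }
    report = {}
    seed = stage_seed(config.seed, "signatures")
    for i, (label, subset) in enumerate(groups.items()):
        snvs = [v for v in subset if v.is_snv]
        if not snvs:
            skips.append({"stage": "signatures", "group": label,
                          "reason": "no SNVs in group"})
            continue
        profile, skipped = profiles.build_profile(subset, label=label)
        result = signatures.bootstrap_decompose(
            profile, catalog, n_boot=config.n_boot, seed=seed + i,
            include_flat=config.include_flat,
        )
        merged = signatures.merge_etiologies(
            result.exposures, catalog.etiology_groups or None,
        )
        report[label] = {
            "n_mutations": profile.total,
            "n_skipped_non_snv": skipped,
            "exposures": result.exposures,
            "bootstrap_mean": result.bootstrap_mean,
            "ci_low": result.ci_low,
            "ci_high": result.ci_high,
            "active": sorted(result.active),
            "merged": merged,
        }
        pd.DataFrame({"Type": catalog.channel_order,
                      label: profile.counts}).to_csv(
            out / f"profile_{label}.tsv", sep="\t", index=False)
    (out / "signature_exposures.json").write_text(json.dumps(report, indent=2))
    counts = {
        "patient_set1": len(partition.patient_set1),
        "patient_set2": len(partition.patient_set2),
        **{k: len(v) for k, v in groups.items()},
    }
    (out / "partition_counts.json").write_text(json.dumps(counts, indent=2))
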