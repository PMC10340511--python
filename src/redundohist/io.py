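"""Readers and writers for the tab-separated inputs of the pipeline.

Supported tables: GDC-dialect MAF variant tables, a simple TSV variant
dialect, the gene registry (gene -> protein accession, CDS length, family),
COSMIC-layout SBS96 signature catalogs, clinical patient tables, gene-level
covariates and driver-gene lists.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import sbs96
from .model import (
    GeneModel,
    HistoneClass,
    HistoneFamily,
    SignatureCatalog,
    VariantClass,
    VariantRecord,
)

logger = logging.getLogger(__name__)

#: GDC MAF Variant_Classification strings -> internal consequence enum.
MAF_CLASSIFICATION_MAP: dict[str, VariantClass] = {
    "Missense_Mutation": VariantClass.MISSENSE,
    "Silent": VariantClass.SILENT,
    "Nonsense_Mutation": VariantClass.NONSENSE,
    "Nonstop_Mutation": VariantClass.NONSTOP,
    "Frame_Shift_Ins": VariantClass.FRAMESHIFT_INSERTION,
    "Frame_Shift_Del": VariantClass.FRAMESHIFT_DELETION,
    "Splice_Site": VariantClass.SPLICE_SITE,
    "Splice_Region": VariantClass.SPLICE_REGION,
    "Translation_Start_Site": VariantClass.TRANSLATION_START_SITE,
}

_MAF_TO_ENUM_LOWER = {k.lower(): v for k, v in MAF_CLASSIFICATION_MAP.items()}
_ENUM_TO_MAF = {v: k for k, v in MAF_CLASSIFICATION_MAP.items()}
_ENUM_TO_MAF[VariantClass.OTHER] = "3'UTR"

MAF_REQUIRED_COLUMNS = (
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
)

SIMPLE_REQUIRED_COLUMNS = (
    "patient_id",
    "gene_symbol",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "classification",
)


def normalize_classification(raw: str) -> VariantClass:
    """Map a classification string (MAF or internal spelling) onto the enum."""
    raw = raw.strip()
    hit = _MAF_TO_ENUM_LOWER.get(raw.lower())
    if hit is not None:
        return hit
    try:
        return VariantClass(raw.lower())
    except ValueError:
        return VariantClass.OTHER


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_clinical(path: str | Path) -> dict[str, str]:
    """Two-column clinical table: patient_id, cancer_type."""
    df = _read_table(path)
    for col in ("patient_id", "cancer_type"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    return dict(zip(df["patient_id"], df["cancer_type"]))


def read_variants(
    path: str | Path,
    dialect: str = "maf",
    clinical: dict[str, str] | None = None,
) -> list[VariantRecord]:
    """Read a somatic variant table into VariantRecords.

    ``dialect='maf'`` expects GDC MAF column names; ``dialect='simple_tsv'``
    expects the internal lowercase column names. Unknown classification
    strings are retained as ``other``. A clinical patient->cancer_type map,
    if given, wins over any cancer_type column in the file (warning on
    conflict). Context columns are validated: for SNVs the middle base must
    equal the reference allele.
    """
    df = _read_table(path)
    if dialect == "maf":
        required = MAF_REQUIRED_COLUMNS
        colmap = dict(
            patient="Tumor_Sample_Barcode",
            gene="Hugo_Symbol",
            chrom="Chromosome",
            pos="Start_Position",
            ref="Reference_Allele",
            alt="Tumor_Seq_Allele2",
            cls="Variant_Classification",
        )
        context_col = "CONTEXT" if "CONTEXT" in df.columns else None
        cancer_col = "Cancer_Type" if "Cancer_Type" in df.columns else None
    elif dialect == "simple_tsv":
        required = SIMPLE_REQUIRED_COLUMNS
        colmap = dict(
            patient="patient_id",
            gene="gene_symbol",
            chrom="chrom",
            pos="pos",
            ref="ref_allele",
            alt="alt_allele",
            cls="classification",
        )
        context_col = "context" if "context" in df.columns else None
        cancer_col = "cancer_type" if "cancer_type" in df.columns else None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for col in required:
        if col not in df.columns:
            raise ValueError(f"variant table {path} missing required column {col!r}")

    records: list[VariantRecord] = []
    bad_context_lines: list[int] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            pos = int(row[colmap["pos"]])
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: unparseable position "
                             f"{row[colmap['pos']]!r}") from exc
        context = None
        if context_col:
            raw_ctx = row[context_col].strip()
            context = raw_ctx if raw_ctx and raw_ctx != "-" else None
        cancer_type = row[cancer_col] if cancer_col else ""
        patient = row[colmap["patient"]]
        if clinical and patient in clinical:
            if cancer_type and cancer_type != clinical[patient]:
                logger.warning(
                    "cancer type conflict for %s (%s vs clinical %s); clinical wins",
                    patient, cancer_type, clinical[patient],
                )
            cancer_type = clinical[patient]
        try:
            records.append(
                VariantRecord(
                    patient_id=patient,
                    gene_symbol=row[colmap["gene"]],
                    chrom=str(row[colmap["chrom"]]),
                    pos=pos,
                    ref_allele=row[colmap["ref"]],
                    alt_allele=row[colmap["alt"]],
                    classification=normalize_classification(row[colmap["cls"]]),
                    cancer_type=cancer_type,
                    context=context,
                )
            )
        except ValueError as exc:
            if "middle base" in str(exc):
                bad_context_lines.append(i)
            else:
                raise ValueError(f"{path} line {i}: {exc}") from exc
    if bad_context_lines:
        raise ValueError(
            f"{path}: context middle base mismatches ref allele on lines "
            f"{bad_context_lines}"
        )
    return records


def write_variants_maf(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records as a GDC-dialect MAF (with CONTEXT and Cancer_Type columns)."""
    rows = [
        {
            "Hugo_Symbol": r.gene_symbol,
            "Chromosome": r.chrom,
            "Start_Position": r.pos,
            "Reference_Allele": r.ref_allele,
            "Tumor_Seq_Allele2": r.alt_allele,
            "Variant_Classification": _ENUM_TO_MAF[r.classification],
            "Tumor_Sample_Barcode": r.patient_id,
            "Cancer_Type": r.cancer_type,
            "CONTEXT": r.context if r.context is not None else "-",
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
            "Tumor_Seq_Allele2", "Variant_Classification",
            "Tumor_Sample_Barcode", "Cancer_Type", "CONTEXT",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_registry(path: str | Path) -> list[GeneModel]:
    df = _read_table(path)
    required = ("gene_symbol", "protein_accession", "cds_length",
                "family", "histone_class", "chrom")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"registry {path} missing required column {col!r}")
    return [
        GeneModel(
            gene_symbol=row.gene_symbol,
            protein_accession=row.protein_accession,
            cds_length=int(row.cds_length),
            family=HistoneFamily(row.family),
            histone_class=HistoneClass(row.histone_class),
            chrom=str(row.chrom),
        )
        for row in df.itertuples(index=False)
    ]


def write_registry(registry: Sequence[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_symbol": g.gene_symbol,
                "protein_accession": g.protein_accession,
                "cds_length": g.cds_length,
                "family": g.family.value,
                "histone_class": g.histone_class.value,
                "chrom": g.chrom,
            }
            for g in registry
        ]
    ).to_csv(path, sep="\t", index=False)


def read_signature_catalog(
    path: str | Path,
    etiology_groups: dict[str, list[str]] | None = None,
) -> SignatureCatalog:
    """Read a COSMIC-layout SBS96 catalog ("Type" column like ``A[C>A]A``).

    Rows may arrive in any order; they are mapped onto the canonical channel
    ordering. Columns must be nonnegative and sum to 1 within 1e-3 (they are
    renormalized); exactly 96 context rows are required.
    """
    df = pd.read_csv(path, sep="\t")
    type_col = df.columns[0]
    if len(df) != 96:
        raise ValueError(f"catalog {path} has {len(df)} context rows, expected 96")
    labels = list(df[type_col])
    if set(labels) != set(sbs96.CHANNELS):
        missing = sorted(set(sbs96.CHANNELS) - set(labels))[:5]
        raise ValueError(f"catalog {path} channel labels invalid; e.g. missing {missing}")
    df = df.set_index(type_col).loc[list(sbs96.CHANNELS)]
    matrix = df.to_numpy(dtype=float)
    return SignatureCatalog(
        matrix=matrix,
        signature_names=list(df.columns),
        etiology_groups=etiology_groups or {},
    )


def write_signature_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    df = pd.DataFrame(catalog.matrix, columns=catalog.signature_names)
    df.insert(0, "Type", list(sbs96.CHANNELS))
    df.to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Gene-level covariate table: gene_symbol, expression, replication_time, chromatin_state."""
    df = pd.read_csv(path, sep="\t")
    if "gene_symbol" not in df.columns:
        raise ValueError(f"covariate table {path} missing gene_symbol column")
    return df.set_index("gene_symbol")


def read_driver_list(path: str | Path) -> list[str]:
    """Driver gene list: one symbol per line, '#' comments allowed."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.append(line)
    return symbols


def read_driver_mutations(path: str | Path) -> set[tuple[str, int, str]]:
    """Driver-mutation positions: TSV with gene, chrom, pos, alt columns."""
    df = _read_table(path)
    for col in ("gene", "pos", "alt"):
        if col not in df.columns:
            raise ValueError(f"driver mutation table {path} missing column {col!r}")
    return {(r.gene, int(r.pos), r.alt) for r in df.itertuples(index=False)}
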