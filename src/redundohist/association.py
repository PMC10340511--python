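"""Mutation co-occurrence testing and covariate correlation.

The co-occurrence question: are patients carrying a mutation in a query gene
(e.g. the replicative polymerase POLE) more likely to also carry a histone
gene mutation? Patients are cross-classified into a 2x2 table
(query-mutated x histone-mutated) and tested with the one-sided exact
hypergeometric (Fisher) test; the effect is the odds ratio ad/bc, with the
Haldane 0.5 correction applied only when a zero cell occurs.

The covariate question: does the per-gene mutation rate m_i/c_i track
genomic covariates (expression, replication time, chromatin state)?
Quantified by the Pearson correlation with its two-sided t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import COUNTED_CLASSES, GeneModel, VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]  # [[a, b], [c, d]]
    odds_ratio: float  # may be inf
    p_one_sided: float
    direction: str = "greater"
    haldane_corrected: bool = False
    degenerate: bool = False


def _odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    if min(a, b, c, d) == 0:
        logger.info("zero cell in 2x2 table; applying Haldane 0.5 correction")
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a2 * d2) / (b2 * c2), True
    return (a * d) / (b * c), False


def cooccurrence_from_flags(
    query_flags: np.ndarray,
    histone_flags: np.ndarray,
    direction: str = "greater",
) -> ContingencyResult:
    """Exact one-sided Fisher test from per-patient boolean indicators."""
    q = np.asarray(query_flags, dtype=bool)
    h = np.asarray(histone_flags, dtype=bool)
    if q.shape != h.shape:
        raise ValueError("flag vectors must be the same length")
    a = int((q & h).sum())
    b = int((q & ~h).sum())
    c = int((~q & h).sum())
    d = int((~q & ~h).sum())
    table = ((a, b), (c, d))
    if min(a + b, c + d, a + c, b + d) == 0:
        return ContingencyResult(table=table, odds_ratio=_odds_ratio(a, b, c, d)[0],
                                 p_one_sided=1.0, direction=direction,
                                 degenerate=True)
    p = float(stats.fisher_exact(np.array(table), alternative=direction)[1])
    odds, haldane = _odds_ratio(a, b, c, d)
    return ContingencyResult(table=table, odds_ratio=odds, p_one_sided=p,
                             direction=direction, haldane_corrected=haldane)


def cooccurrence_test(
    variants: Sequence[VariantRecord],
    registry: Sequence[GeneModel],
    query_genes: Iterable[str],
    patients: Iterable[str] | None = None,
    restrict_to_driver_positions: set[tuple[str, int, str]] | None = None,
    direction: str = "greater",
) -> ContingencyResult:
    """2x2 co-occurrence of query-gene and histone-gene mutations.

    ``patients`` should be the full cohort (clinical table keys) so that
    patients without any call populate the neither-cell; defaults to the
    patients observed in ``variants``. With ``restrict_to_driver_positions``
    only (gene, pos, alt)-matching calls count on the query axis.
    """
    query_set = set(query_genes)
    histone_genes = {g.gene_symbol for g in registry if g.is_histone}
    if patients is None:
        patients = {v.patient_id for v in variants}
    patient_list = sorted(set(patients))
    idx = {p: i for i, p in enumerate(patient_list)}
    q = np.zeros(len(patient_list), dtype=bool)
    h = np.zeros(len(patient_list), dtype=bool)
    for v in variants:
        if v.patient_id not in idx or v.classification not in COUNTED_CLASSES:
            continue
        i = idx[v.patient_id]
        if v.gene_symbol in query_set:
            if restrict_to_driver_positions is None or (
                (v.gene_symbol, v.pos, v.alt_allele) in restrict_to_driver_positions
            ):
                q[i] = True
        if v.gene_symbol in histone_genes:
            h[i] = True
    return cooccurrence_from_flags(q, h, direction=direction)


@dataclass(frozen=True)
class CovariateCorrelation:
    covariate: str
    pcc: float
    p: float
    n_genes: int
    defined: bool = True


def covariate_correlation(
    gene_rates: Mapping[str, float],
    covariates: pd.DataFrame,
    covariate_names: Sequence[str] = ("expression", "replication_time",
                                     "chromatin_state"),
) -> list[CovariateCorrelation]:
    """Pearson correlation of per-gene rate against each covariate.

    Genes missing a covariate are dropped pairwise (logged). Zero variance
    in either vector yields an undefined, flagged result. Requires at least
    three genes with both values.
    """
    results = []
    for name in covariate_names:
        if name not in covariates.columns:
            raise ValueError(f"covariate table lacks column {name!r}")
        pairs = [
            (rate, covariates.at[g, name])
            for g, rate in gene_rates.items()
            if g in covariates.index and pd.notna(covariates.at[g, name])
        ]
        dropped = len(gene_rates) - len(pairs)
        if dropped:
            logger.info("covariate %s: dropped %d genes without a value",
                        name, dropped)
        if len(pairs) < 3:
            raise ValueError(f"covariate {name!r}: fewer than 3 genes with values")
        x = np.array([p[0] for p in pairs], dtype=float)
        y = np.array([p[1] for p in pairs], dtype=float)
        if x.std() == 0 or y.std() == 0:
            results.append(CovariateCorrelation(covariate=name, pcc=np.nan,
                                                p=np.nan, n_genes=len(pairs),
                                                defined=False))
            continue
        pcc, p = stats.pearsonr(x, y)
        results.append(CovariateCorrelation(covariate=name, pcc=float(pcc),
                                            p=float(p), n_genes=len(pairs)))
    return results
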