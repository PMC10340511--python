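"""Chi-squared homogeneity of mutation counts across genes encoding one protein.

The unit counted is patients-with-a-mutation per gene. Under the null the
expected counts are proportional to CDS length (``null="length"``; for the
identical-length paralogs typical of histone families this reduces to the
uniform null, also available as ``null="uniform"``). When any expected cell
falls below 5 the asymptotic chi-squared reference is unreliable for these
sparse tables, and the p-value is obtained by Monte-Carlo simulation instead:
tables are redrawn multinomially from the null at the observed total and

    p = (1 + #{simulated chi2 >= observed chi2}) / (n_sim + 1)

(the +1/+1 correction keeps p strictly positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .compare import bh_adjust
from .model import GeneMutationCount, GeneModel, ProteinGroup, build_protein_groups
from .rates import PAN_CANCER, count_mutations, eligible_cancer_types


@dataclass
class HomogeneityTable:
    protein_accession: str
    cancer_type: str
    gene_symbols: list[str]
    observed: list[int]
    expected: list[float]
    method: str  # "asymptotic" | "monte_carlo"
    n_sim: int
    chi2: float
    p: float


def homogeneity_test(
    group: ProteinGroup,
    counts: Sequence[GeneMutationCount] | Mapping[str, int],
    n_sim: int = 10_000,
    seed: int | None = None,
    null: str = "length",
    expected_threshold: float = 5.0,
) -> HomogeneityTable | None:
    """Goodness-of-fit chi-squared for one protein group; MC fallback when sparse.

    ``counts`` maps gene -> patients-with-a-mutation (GeneMutationCount
    sequences use their ``patients_mutated`` field). Returns None (skipped)
    when the group has fewer than two genes or zero total mutations.
    """
    if isinstance(counts, Mapping):
        by_gene = dict(counts)
    else:
        by_gene = {c.gene_symbol: c.patients_mutated for c in counts}
    genes = [g.gene_symbol for g in group.member_genes]
    observed = np.array([by_gene.get(g, 0) for g in genes], dtype=float)
    if len(genes) < 2 or observed.sum() == 0:
        return None

    if null == "length":
        weights = np.array([g.cds_length for g in group.member_genes], dtype=float)
    elif null == "uniform":
        weights = np.ones(len(genes))
    else:
        raise ValueError(f"unknown null model {null!r}")
    probs = weights / weights.sum()
    total = observed.sum()
    expected = total * probs
    chi2 = float(((observed - expected) ** 2 / expected).sum())

    if expected.min() < expected_threshold:
        rng = np.random.default_rng(seed)
        sims = rng.multinomial(int(total), probs, size=n_sim)
        sim_chi2 = ((sims - expected) ** 2 / expected).sum(axis=1)
        p = (1 + int((sim_chi2 >= chi2 - 1e-12).sum())) / (n_sim + 1)
        method = "monte_carlo"
    else:
        p = float(stats.chi2.sf(chi2, df=len(genes) - 1))
        method = "asymptotic"
        n_sim = 0
    return HomogeneityTable(
        protein_accession=group.protein_accession,
        cancer_type=PAN_CANCER,
        gene_symbols=genes,
        observed=[int(o) for o in observed],
        expected=expected.tolist(),
        method=method,
        n_sim=n_sim,
        chi2=chi2,
        p=p,
    )


def homogeneity_scan(
    variants,
    registry: Sequence[GeneModel],
    clinical: Mapping[str, str] | None = None,
    min_patients: int = 10,
    n_sim: int = 10_000,
    seed: int | None = None,
    null: str = "length",
    histone_only: bool = True,
) -> pd.DataFrame:
    """Homogeneity tests for every multi-gene protein, pan-cancer and per type.

    BH q-values are computed across proteins within each cancer type.
    """
    groups = [
        g for g in build_protein_groups(registry)
        if g.n >= 2 and (g.is_histone or not histone_only)
    ]
    cancer_types: list[str | None] = [None]
    if clinical is not None:
        cancer_types += sorted(eligible_cancer_types(clinical, min_patients))
    rows = []
    for ct in cancer_types:
        counts = count_mutations(variants, registry, cancer_type=ct)
        label = ct if ct is not None else PAN_CANCER
        for i, group in enumerate(groups):
            table = homogeneity_test(
                group, counts, n_sim=n_sim,
                seed=None if seed is None else seed + i, null=null,
            )
            if table is None:
                continue
            rows.append(
                {
                    "protein_accession": group.protein_accession,
                    "cancer_type": label,
                    "n_genes": group.n,
                    "total_patients_mutated": sum(table.observed),
                    "method": table.method,
                    "chi2": table.chi2,
                    "p": table.p,
                }
            )
    result = pd.DataFrame(rows)
    if not result.empty:
        result["q"] = np.nan
        for ct in result["cancer_type"].unique():
            mask = result["cancer_type"] == ct
            result.loc[mask, "q"] = bh_adjust(result.loc[mask, "p"].to_numpy())
    return result
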