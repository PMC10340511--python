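"""Rank-based group comparisons of protein-level mutation rates.

The sampling unit is the protein: one pooled rate r per protein per cancer
type. Histone proteins are compared against non-histone proteins (or against
a driver-protein set) with the Mann-Whitney U test; families are compared
with Kruskal-Wallis plus a Dunn post-hoc; p-values are Benjamini-Hochberg
adjusted per analysis family. Fold change is reported as
mean(group A) / mean(group B).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import HISTONE_FAMILIES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwoGroupResult:
    statistic: float  # Mann-Whitney U for the first group
    p: float
    fold_change: float | None  # mean(a)/mean(b); None when a mean is 0


@dataclass(frozen=True)
class KGroupResult:
    statistic: float  # Kruskal-Wallis H (tie-corrected)
    p: float
    dunn: pd.DataFrame | None  # pairwise z / p / q, present when KW p < alpha


def compare_two_groups(
    rates_a: list[float] | np.ndarray,
    rates_b: list[float] | np.ndarray,
) -> TwoGroupResult:
    """Two-sided Mann-Whitney U with fold change mean(a)/mean(b).

    The exact null distribution is enumerated for small tie-free samples
    (n_a * n_b <= 200); otherwise the tie- and continuity-corrected normal
    approximation is used.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size * b.size <= 200 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    mean_a, mean_b = a.mean(), b.mean()
    fold = (mean_a / mean_b) if (mean_a > 0 and mean_b > 0) else None
    return TwoGroupResult(statistic=float(res.statistic), p=float(res.pvalue),
                          fold_change=fold)


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-aligned with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks, BH-adjusted."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    rank_means: dict[str, float] = {}
    start = 0
    for g in labels:
        size = groups[g].size
        rank_means[g] = ranks[start:start + size].mean()
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12 - tie_term
    rows = []
    for ga, gb in itertools.combinations(labels, 2):
        se = math.sqrt(base_var * (1 / groups[ga].size + 1 / groups[gb].size))
        z = (rank_means[ga] - rank_means[gb]) / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"group_a": ga, "group_b": gb, "z": z, "p": p})
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table


def compare_k_groups(
    groups: dict[str, list[float] | np.ndarray],
    dunn_alpha: float = 0.05,
) -> KGroupResult:
    """Kruskal-Wallis H across k groups; Dunn post-hoc when KW p < alpha.

    All observations identical across groups is the degenerate case: H = 0,
    p = 1 (no evidence of any difference).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if any(a.size == 0 for a in arrays.values()):
        raise ValueError("all groups must be nonempty")
    pooled = np.concatenate(list(arrays.values()))
    if np.all(pooled == pooled[0]):
        return KGroupResult(statistic=0.0, p=1.0, dunn=None)
    h, p = stats.kruskal(*arrays.values())
    dunn = _dunn_posthoc(arrays) if p < dunn_alpha else None
    return KGroupResult(statistic=float(h), p=float(p), dunn=dunn)


def histone_vs_group_comparison(
    rates: pd.DataFrame,
    comparison: str = "non_histone",
    driver_proteins: set[str] | None = None,
) -> pd.DataFrame:
    """Per-cancer-type histone-vs-comparison Mann-Whitney scan with BH control.

    ``rates`` is the protein_rates_table output. ``comparison`` selects the
    contrast group: every non-histone protein, or (``"drivers"``) a supplied
    driver-protein accession set with histone proteins excluded from it.
    Returns a volcano-ready table (fold_change, p, q, minus_log10_q).
    """
    rows = []
    for ct, sub in rates.groupby("cancer_type"):
        hist = sub.loc[sub["is_histone"], "r"].to_numpy()
        if comparison == "drivers":
            if driver_proteins is None:
                raise ValueError("driver comparison requires driver_proteins")
            mask = sub["protein_accession"].isin(driver_proteins) & ~sub["is_histone"]
            other = sub.loc[mask, "r"].to_numpy()
        else:
            other = sub.loc[~sub["is_histone"], "r"].to_numpy()
        if hist.size == 0 or other.size == 0:
            logger.info("skipping %s: empty contrast group", ct)
            continue
        res = compare_two_groups(hist, other)
        rows.append(
            {
                "cancer_type": ct,
                "group_a": "histone",
                "group_b": comparison,
                "test": "mann_whitney_u",
                "statistic": res.statistic,
                "p": res.p,
                "fold_change": res.fold_change,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["q"] = bh_adjust(table["p"].to_numpy())
        with np.errstate(divide="ignore"):
            table["minus_log10_q"] = -np.log10(table["q"])
    return table


def family_comparison(
    rates: pd.DataFrame,
    family_mutation_totals: pd.DataFrame,
    min_mutations: int = 10,
) -> tuple[pd.DataFrame, list[dict]]:
    """Kruskal-Wallis across the five histone families per cancer type.

    A cancer type enters only if every family has at least ``min_mutations``
    counted mutations there; excluded types are returned with the reason.
    ``family_mutation_totals`` columns: cancer_type, family, m_total.
    """
    families = [f.value for f in HISTONE_FAMILIES]
    skipped: list[dict] = []
    rows = []
    for ct, sub in rates[rates["is_histone"]].groupby("cancer_type"):
        totals = family_mutation_totals[
            family_mutation_totals["cancer_type"] == ct
        ].set_index("family")["m_total"]
        low = [f for f in families if totals.get(f, 0) < min_mutations]
        if low:
            reason = {f: int(totals.get(f, 0)) for f in low}
            skipped.append({"cancer_type": ct,
                            "reason": f"families below {min_mutations} mutations",
                            "families": reason})
            logger.info("family comparison skipped for %s: %s", ct, reason)
            continue
        groups = {
            f: sub.loc[sub["family"] == f, "r"].to_numpy() for f in families
        }
        groups = {f: v for f, v in groups.items() if v.size > 0}
        if len(groups) < 2:
            skipped.append({"cancer_type": ct, "reason": "fewer than 2 families"})
            continue
        res = compare_k_groups(groups)
        rows.append({"cancer_type": ct, "test": "kruskal_wallis",
                     "statistic": res.statistic, "p": res.p})
    table = pd.DataFrame(rows)
    if not table.empty:
        table["q"] = bh_adjust(table["p"].to_numpy())
    return table, skipped
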