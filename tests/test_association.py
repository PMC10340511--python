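"""Co-occurrence contingency testing and covariate correlation."""

import math

import numpy as np
import pandas as pd
import pytest

from redundohist import (
    VariantClass,
    VariantRecord,
    cooccurrence_from_flags,
    cooccurrence_test,
    covariate_correlation,
)
from redundohist.simulate import (
    default_registry_spec,
    make_registry,
)


def _flags(a, b, c, d):
    q = np.array([True] * (a + b) + [False] * (c + d))
    h = np.array([True] * a + [False] * b + [True] * c + [False] * d)
    return q, h


def _hypergeom_sf_enumeration(a, b, c, d):
    """Independent oracle: P(X >= a) by direct summation of the hypergeometric."""
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    denom = math.comb(n_total, col1)
    p = 0.0
    for x in range(a, min(row1, col1) + 1):
        p += math.comb(row1, x) * math.comb(n_total - row1, col1 - x) / denom
    return p


class TestCooccurrence:
    def test_enriched_table_odds_ratio_and_exact_p(self):
        result = cooccurrence_from_flags(*_flags(30, 10, 10, 30))
        assert result.odds_ratio == pytest.approx(9.0)
        assert result.p_one_sided == pytest.approx(
            _hypergeom_sf_enumeration(30, 10, 10, 30), rel=1e-9)
        assert not result.haldane_corrected

    def test_p_equals_one_minus_hypergeom_cdf(self):
        from scipy.stats import hypergeom
        a, b, c, d = 12, 20, 8, 60
        result = cooccurrence_from_flags(*_flags(a, b, c, d))
        expected = float(hypergeom.sf(a - 1, a + b + c + d, a + b, a + c))
        assert result.p_one_sided == pytest.approx(expected, rel=1e-12)

    def test_haldane_only_on_zero_cell(self):
        zero = cooccurrence_from_flags(*_flags(10, 0, 5, 20))
        assert zero.haldane_corrected
        assert zero.odds_ratio == pytest.approx((10.5 * 20.5) / (0.5 * 5.5))
        nonzero = cooccurrence_from_flags(*_flags(10, 2, 5, 20))
        assert not nonzero.haldane_corrected

    def test_degenerate_margin_flagged(self):
        result = cooccurrence_from_flags(*_flags(0, 0, 10, 30))
        assert result.degenerate
        assert result.p_one_sided == 1.0

    def test_row_column_swap_symmetry(self):
        fwd = cooccurrence_from_flags(*_flags(30, 10, 10, 30))
        q, h = _flags(30, 10, 10, 30)
        swapped = cooccurrence_from_flags(h, q)
        assert swapped.odds_ratio == pytest.approx(fwd.odds_ratio)
        assert swapped.p_one_sided == pytest.approx(fwd.p_one_sided)

    def test_variant_level_interface_with_driver_restriction(self):
        registry = make_registry(default_registry_spec(n_background=2))
        patients = [f"P{i}" for i in range(6)]

        def snv(p, gene, pos):
            return VariantRecord(p, gene, "1", pos, "C", "T",
                                 VariantClass.MISSENSE)

        variants = [
            snv("P0", "POLE", 100), snv("P0", "H4C1", 10),
            snv("P1", "POLE", 200), snv("P2", "H4C2", 20),
        ]
        res = cooccurrence_test(variants, registry, ["POLE"],
                                patients=patients)
        assert res.table == ((1, 1), (1, 3))
        drivers = {("POLE", 100, "T")}
        restricted = cooccurrence_test(variants, registry, ["POLE"],
                                       patients=patients,
                                       restrict_to_driver_positions=drivers)
        # P1's POLE call at pos 200 no longer counts on the query axis
        assert restricted.table == ((1, 0), (1, 4))


class TestCovariateCorrelation:
    COLS = ["expression", "replication_time", "chromatin_state"]

    def _cov(self, genes, **columns):
        frame = {c: columns.get(c, np.linspace(0, 1, len(genes)))
                 for c in self.COLS}
        return pd.DataFrame(frame, index=pd.Index(genes, name="gene_symbol"))

    def test_exact_linear_relationship(self):
        genes = [f"G{i}" for i in range(10)]
        rates = {g: 0.001 * (i + 1) for i, g in enumerate(genes)}
        cov = self._cov(genes,
                        replication_time=np.array(
                            [2 * rates[g] for g in genes]))
        results = {c.covariate: c for c in covariate_correlation(rates, cov)}
        assert results["replication_time"].pcc == pytest.approx(1.0)
        assert results["replication_time"].n_genes == 10

    def test_zero_variance_flagged_undefined(self):
        genes = [f"G{i}" for i in range(5)]
        rates = {g: 0.001 * (i + 1) for i, g in enumerate(genes)}
        cov = self._cov(genes, chromatin_state=np.zeros(5))
        results = {c.covariate: c for c in covariate_correlation(rates, cov)}
        assert not results["chromatin_state"].defined

    def test_missing_genes_dropped_pairwise(self):
        genes = [f"G{i}" for i in range(8)]
        rates = {g: 0.001 * (i + 1) for i, g in enumerate(genes + ["ABSENT"])}
        cov = self._cov(genes)
        results = covariate_correlation(rates, cov)
        assert all(r.n_genes == 8 for r in results)

    def test_too_few_genes_rejected(self):
        rates = {"G0": 0.1, "G1": 0.2}
        cov = self._cov(["G0", "G1"])
        with pytest.raises(ValueError, match="fewer than 3"):
            covariate_correlation(rates, cov)

    def test_independent_covariate_shows_no_correlation(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(1000)]
        rates = {g: float(r) for g, r in zip(genes, rng.lognormal(0, 1, 1000))}
        cov = self._cov(genes, expression=rng.normal(0, 1, 1000))
        results = {c.covariate: c for c in covariate_correlation(rates, cov)}
        assert abs(results["expression"].pcc) < 0.08
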