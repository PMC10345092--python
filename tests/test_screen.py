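import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import brute_force_bh
from phenoscreen.io import ExpressionMatrix, GeneSet
from phenoscreen.screen import (
    benjamini_hochberg,
    build_heatmap_bundle,
    correlated_gene_summary,
    per_gene_association,
    screen_gene_set,
)


def _matrix_from(values, cells=None, genes=None):
    values = np.asarray(values, dtype=float)
    cells = cells or [f"c{i}" for i in range(values.shape[0])]
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(cells, genes, values, "log10cpm1")


def _phenotypes(values, cells=None, which="tdl"):
    cells = cells or [f"c{i}" for i in range(len(values))]
    return pd.DataFrame({"cell_id": cells, which: values})


class TestPerGeneAssociation:
    def test_perfect_linear_gene(self, rng):
        y = np.linspace(1000, 5000, 10)
        x = (0.001 * y)[:, None]
        records, dropped = per_gene_association(
            _matrix_from(x), _phenotypes(y), "tdl", GeneSet("s", frozenset(["g0"]))
        )
        assert records[0].r == pytest.approx(1.0)
        assert records[0].p < 1e-12 and records[0].sign == "+"

    def test_constant_gene_dropped(self):
        y = np.array([1000.0, 2000, 3000, 4000])
        x = np.column_stack([np.full(4, 2.0), y / 1000])
        records, dropped = per_gene_association(
            _matrix_from(x), _phenotypes(y), "tdl", GeneSet("s", frozenset(["g0", "g1"]))
        )
        assert dropped == ["g0"]
        assert [r.gene for r in records] == ["g1"]

    def test_p_equals_pearson_t_test(self, rng):
        # closed form: n=20, r=0.5 -> t = 2.449, two-sided p ~ 0.0249
        # construct data with exactly r = 0.5 via Gram-Schmidt
        n = 20
        y = rng.normal(size=n)
        e = rng.normal(size=n)
        y_std = (y - y.mean()) / y.std()
        e_res = e - e.mean() - np.dot(e - e.mean(), y_std) / n * y_std
        e_std = e_res / np.sqrt((e_res**2).mean())
        r_target = 0.5
        x = r_target * y_std + np.sqrt(1 - r_target**2) * e_std
        x = x - x.min() + 0.1  # keep expression nonnegative
        y_ph = y_std - y_std.min() + 1.0  # shift preserves the correlation
        records, _ = per_gene_association(
            _matrix_from(x[:, None]), _phenotypes(y_ph), "tdl",
            GeneSet("s", frozenset(["g0"])),
        )
        rec = records[0]
        assert rec.r == pytest.approx(0.5, abs=1e-9)
        t = rec.r * np.sqrt(n - 2) / np.sqrt(1 - rec.r**2)
        assert t == pytest.approx(2.449, abs=1e-3)
        assert rec.p == pytest.approx(2 * stats.t.sf(t, n - 2), rel=1e-10)
        assert rec.p == pytest.approx(0.0249, abs=2e-4)

    def test_ols_slope_p_equals_pearson_p(self, rng):
        """The OLS slope t test and the correlation t test are the same test."""
        for _ in range(200):
            n = int(rng.integers(5, 30))
            y = rng.normal(size=n)
            x = rng.normal(size=(n, 1)) ** 2
            records, _ = per_gene_association(
                _matrix_from(x), _phenotypes(y - y.min() + 1, which="ap_rise_speed"),
                "ap_rise_speed", GeneSet("s", frozenset(["g0"])),
            )
            lr = stats.linregress(y, x[:, 0])
            assert records[0].p == pytest.approx(lr.pvalue, abs=1e-10)
            assert records[0].slope == pytest.approx(lr.slope, rel=1e-9)

    def test_cells_missing_phenotype_excluded(self):
        x = np.arange(8, dtype=float)[:, None]
        ph = _phenotypes([1.0, 2, 3, 4, np.nan, np.nan, np.nan, np.nan])
        records, _ = per_gene_association(
            _matrix_from(x), ph, "tdl", GeneSet("s", frozenset(["g0"]))
        )
        assert records[0].n == 4

    def test_constant_phenotype_is_error(self):
        x = np.arange(5, dtype=float)[:, None]
        with pytest.raises(ValueError, match="constant"):
            per_gene_association(
                _matrix_from(x), _phenotypes([3.0] * 5), "tdl",
                GeneSet("s", frozenset(["g0"])),
            )

    def test_no_shared_cells_is_error(self):
        x = np.arange(4, dtype=float)[:, None]
        ph = _phenotypes([1.0, 2.0], cells=["other1", "other2"])
        with pytest.raises(ValueError, match="no cells shared"):
            per_gene_association(_matrix_from(x), ph, "tdl", GeneSet("s", frozenset(["g0"])))


class TestBenjaminiHochberg:
    def test_step_up_worked_example(self):
        fdr, flags = benjamini_hochberg([0.001, 0.01, 0.02, 0.03, 0.04], q=0.05)
        assert fdr.critical_p == pytest.approx(0.04)
        assert fdr.n_significant == 5 and flags.all()

    def test_nothing_significant(self):
        fdr, flags = benjamini_hochberg([0.9, 0.95, 1.0])
        assert fdr.critical_p == 0.0 and not flags.any()

    def test_single_p(self):
        fdr, flags = benjamini_hochberg([0.04], q=0.05)
        assert fdr.critical_p == pytest.approx(0.04) and flags[0]

    def test_empty_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            benjamini_hochberg([])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(500):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            fdr, flags = benjamini_hochberg(p, q=0.05)
            critical, expected_flags = brute_force_bh(p, 0.05)
            assert fdr.critical_p == pytest.approx(critical, abs=1e-12)
            assert np.array_equal(flags, expected_flags)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_flag_count_consistency(self, p):
        fdr, flags = benjamini_hochberg(p)
        assert fdr.n_significant == flags.sum()
        assert fdr.critical_p <= fdr.q or fdr.critical_p == 0.0


class TestHeatmapBundle:
    def _screened(self, rng):
        n = 30
        y = np.sort(rng.uniform(1000, 8000, n))
        x = np.column_stack([
            0.5 * y / 1000 + rng.normal(0, 0.2, n),
            -0.3 * y / 1000 + rng.normal(0, 0.2, n) + 4,
            rng.normal(2, 1, n),
        ])
        x -= x.min()
        m = _matrix_from(x)
        ph = _phenotypes(y)
        records, fdr, _ = screen_gene_set(m, ph, "tdl", GeneSet("s", frozenset(m.gene_ids)))
        return m, ph, records

    def test_rows_are_z_scored(self, rng):
        m, ph, records = self._screened(rng)
        bundle = build_heatmap_bundle(m, ph, "tdl", records)
        np.testing.assert_allclose(bundle.matrix.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(bundle.matrix.std(axis=1), 1, atol=1e-9)

    def test_columns_sorted_by_phenotype_then_id(self, rng):
        m, ph, records = self._screened(rng)
        ph.loc[0, "tdl"] = ph.loc[1, "tdl"]  # force a tie
        bundle = build_heatmap_bundle(m, ph, "tdl", records)
        assert np.all(np.diff(bundle.phenotype) >= 0)
        tied = [c for c in bundle.cell_order
                if ph.set_index("cell_id").loc[c, "tdl"] == ph.loc[0, "tdl"]]
        assert tied == sorted(tied)

    def test_rows_sorted_by_raw_p(self, rng):
        m, ph, records = self._screened(rng)
        bundle = build_heatmap_bundle(m, ph, "tdl", records)
        p_by_gene = {r.gene: r.p for r in records}
        ps = [p_by_gene[g] for g in bundle.gene_order]
        assert ps == sorted(ps)

    def test_partition_by_sign(self, rng):
        m, ph, records = self._screened(rng)
        bundle = build_heatmap_bundle(m, ph, "tdl", records)
        assert "g0" in bundle.partition["+"]
        assert "g1" in bundle.partition["-"]


class TestCorrelatedGeneSummary:
    def test_single_gene_summary_is_identity(self, rng, metadata):
        x = rng.uniform(0, 3, size=(4, 2))
        m = _matrix_from(x, cells=list(metadata["cell_id"]))
        from phenoscreen.screen import GeneScreenRecord

        records = [GeneScreenRecord("g0", 4, 1.0, 0.9, 0.001, True)]
        df, res = correlated_gene_summary(m, records, metadata, "+", posthoc=False)
        np.testing.assert_allclose(df["mean_expression"], x[:, 0])

    def test_empty_sign_returns_empty(self, rng, metadata):
        m = _matrix_from(rng.uniform(0, 3, (4, 1)), cells=list(metadata["cell_id"]))
        from phenoscreen.screen import GeneScreenRecord

        records = [GeneScreenRecord("g0", 4, 1.0, 0.9, 0.001, True)]
        df, res = correlated_gene_summary(m, records, metadata, "-")
        assert df.empty and res is None
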