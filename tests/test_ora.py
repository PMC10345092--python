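import numpy as np
import pytest
from scipy import stats

from conftest import brute_force_bh, brute_force_hypergeom_tail
from phenoscreen.io import AnnotationCatalog, GeneSet
from phenoscreen.ora import (
    hypergeom_upper_tail,
    over_representation,
    q_values,
    restricted_background_ora,
)


def _genes(prefix, n):
    return [f"{prefix}{i}" for i in range(n)]


class TestHypergeomTail:
    def test_hand_enumerated(self):
        # N=20, K=5, n=4, k=3: [C(5,3)C(15,1) + C(5,4)C(15,0)] / C(20,4)
        #                    = (150 + 5)/4845 = 155/4845
        assert hypergeom_upper_tail(3, 20, 5, 4) == pytest.approx(155 / 4845, rel=1e-12)

    def test_certain_event(self):
        assert hypergeom_upper_tail(4, 10, 10, 4) == pytest.approx(1.0)

    def test_zero_hits_p_one(self):
        assert hypergeom_upper_tail(0, 100, 10, 5) == 1.0

    def test_matches_brute_force_exhaustively(self):
        """Tail equals direct term summation for all parameters with N <= 18."""
        checked = 0
        for N in range(2, 19):
            for K in range(0, N + 1):
                for n in range(1, N + 1):
                    for k in range(0, min(K, n) + 1):
                        expected = brute_force_hypergeom_tail(k, N, K, n)
                        assert hypergeom_upper_tail(k, N, K, n) == pytest.approx(
                            expected, abs=1e-10
                        )
                        checked += 1
        assert checked > 5000

    def test_equals_one_sided_fisher(self, rng):
        for _ in range(200):
            N = int(rng.integers(5, 50))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(0, min(K, n) + 1))
            if n - k > N - K:
                continue
            table = [[k, n - k], [K - k, N - K - (n - k)]]
            _, p = stats.fisher_exact(table, alternative="greater")
            assert hypergeom_upper_tail(k, N, K, n) == pytest.approx(p, abs=1e-10)


class TestOverRepresentation:
    def _catalog(self):
        universe = _genes("u", 94) + ["f0", "f1", "f2", "t0", "t1", "t2"]
        terms = {
            "hit_term": frozenset(["f0", "f1", "f2", "t0", "t1", "t2"]),
            "null_term": frozenset(_genes("u", 20)),
        }
        return AnnotationCatalog(terms), GeneSet("uni", frozenset(universe))

    def test_foreground_and_background_ratios(self):
        catalog, universe = self._catalog()
        fg = GeneSet("fg", frozenset(["f0", "f1", "f2", "u0", "u1"]))
        records = {r.term: r for r in over_representation(fg, catalog, universe)}
        rec = records["hit_term"]
        assert rec.k == 3 and rec.n == 5 and rec.K == 6 and rec.N == 100
        assert rec.foreground_ratio == pytest.approx(0.6)
        assert rec.background_ratio == pytest.approx(0.06)
        assert rec.p == pytest.approx(brute_force_hypergeom_tail(3, 100, 6, 5), rel=1e-10)

    def test_paper_scale_proportions(self):
        """A 9-of-62 foreground against a 372-of-19413 universe term gives the
        14.5% vs 1.9% proportion contrast and a tiny one-sided p."""
        fg_genes = _genes("f", 62)
        term_genes = set(_genes("f", 9)) | set(_genes("bg", 363))
        universe = set(_genes("f", 62)) | set(_genes("bg", 19413 - 62))
        catalog = AnnotationCatalog({"glutamatergic synapse": frozenset(term_genes)})
        records = over_representation(
            GeneSet("fg", frozenset(fg_genes)), catalog,
            GeneSet("uni", frozenset(universe)),
        )
        rec = records[0]
        assert rec.k == 9 and rec.n == 62 and rec.K == 372 and rec.N == 19413
        assert 100 * rec.foreground_ratio == pytest.approx(14.5, abs=0.03)
        assert 100 * rec.background_ratio == pytest.approx(1.9, abs=0.02)
        assert rec.p < 1e-4

    def test_zero_hit_terms_reported_with_p_one(self):
        catalog, universe = self._catalog()
        fg = GeneSet("fg", frozenset(["t0", "t1"]))
        records = {r.term: r for r in over_representation(fg, catalog, universe)}
        assert records["null_term"].k == 0 and records["null_term"].p == 1.0

    def test_disjoint_foreground_is_error(self):
        catalog, universe = self._catalog()
        with pytest.raises(ValueError, match="foreground"):
            over_representation(GeneSet("fg", frozenset(["zzz"])), catalog, universe)

    def test_universe_growth_weakly_decreases_p(self, rng):
        for _ in range(50):
            n_uni = int(rng.integers(20, 60))
            uni = set(_genes("u", n_uni))
            term = set(rng.choice(sorted(uni), size=int(rng.integers(2, 10)), replace=False))
            fg = set(rng.choice(sorted(uni), size=int(rng.integers(2, 10)), replace=False))
            catalog = AnnotationCatalog({"t": frozenset(term)})
            p_small = over_representation(
                GeneSet("fg", frozenset(fg)), catalog, GeneSet("u", frozenset(uni))
            )[0].p
            p_large = over_representation(
                GeneSet("fg", frozenset(fg)), catalog,
                GeneSet("u", frozenset(uni | {"extra_gene"})),
            )[0].p
            assert p_large <= p_small + 1e-12

    def test_bh_adjustment_matches_oracle(self, rng):
        genes = _genes("u", 200)
        terms = {
            f"t{i}": frozenset(rng.choice(genes, size=15, replace=False))
            for i in range(30)
        }
        catalog = AnnotationCatalog(terms)
        fg = GeneSet("fg", frozenset(rng.choice(genes, size=20, replace=False)))
        records = over_representation(fg, catalog, GeneSet("u", frozenset(genes)))
        p = [r.p for r in records]
        critical, flags = brute_force_bh(p, 0.05)
        for rec, flag in zip(records, flags):
            assert (rec.p_adjusted <= 0.05) == bool(
                critical > 0 and rec.p <= critical
            )


class TestQValues:
    def test_few_tests_equal_bh_adjusted(self):
        p = [0.01, 0.2, 0.04]
        q = q_values(p)
        # with m < 20, pi0 = 1 and q is the BH-adjusted p
        expected = [0.03, 0.2, 0.06]
        np.testing.assert_allclose(q, expected)

    def test_qvalues_at_most_bh(self, rng):
        p = rng.uniform(size=100) ** 2
        q = q_values(p)
        bh = q_values(p, min_tests_for_pi0=10**9)  # force pi0 = 1
        assert (q <= bh + 1e-12).all()

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=50)
        q = q_values(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestRestrictedBackground:
    def test_reduces_to_full_universe(self, rng):
        genes = _genes("u", 80)
        terms = {f"t{i}": frozenset(rng.choice(genes, 10, replace=False)) for i in range(5)}
        catalog = AnnotationCatalog(terms)
        fg = GeneSet("fg", frozenset(rng.choice(genes, 12, replace=False)))
        uni = GeneSet("u", frozenset(genes))
        full = over_representation(fg, catalog, uni)
        restricted = restricted_background_ora(fg, catalog, uni)
        for a, b in zip(full, restricted):
            assert a.p == pytest.approx(b.p) and a.k == b.k and a.N == b.N

    def test_foreground_outside_background_excluded(self):
        catalog = AnnotationCatalog({"t": frozenset(["a", "b"])})
        fg = GeneSet("fg", frozenset(["a", "zz"]))
        bg = GeneSet("bg", frozenset(["a", "b", "c", "d"]))
        (rec,) = restricted_background_ora(fg, catalog, bg)
        assert rec.n == 1  # zz not in background

    def test_toy_exact_tail(self):
        bg = _genes("b", 100)
        term = frozenset(bg[:10])
        fg = frozenset(bg[:4] + [bg[50]])  # 4 hits of 5
        catalog = AnnotationCatalog({"t": term})
        (rec,) = restricted_background_ora(
            GeneSet("fg", fg), catalog, GeneSet("bg", frozenset(bg))
        )
        assert rec.p == pytest.approx(brute_force_hypergeom_tail(4, 100, 10, 5), rel=1e-10)

    def test_triple_significance_rule(self):
        # strongly enriched term among many nulls: all three criteria < 0.05
        genes = _genes("u", 500)
        rng = np.random.default_rng(0)
        terms = {f"null{i}": frozenset(rng.choice(genes[50:], 20, replace=False))
                 for i in range(25)}
        terms["enriched"] = frozenset(genes[:25])
        catalog = AnnotationCatalog(terms)
        fg = GeneSet("fg", frozenset(genes[:15]))
        records = {r.term: r for r in
                   over_representation(fg, catalog, GeneSet("u", frozenset(genes)))}
        assert records["enriched"].significant
        assert records["enriched"].p < 0.05
        assert records["enriched"].p_adjusted < 0.05
        assert records["enriched"].q < 0.05
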