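"""Over-representation analysis against GO-style annotation catalogs.

For each annotation term, the foreground list is tested for an excess of term
members via the hypergeometric upper tail P(X >= k) — equivalent to a
one-sided Fisher exact test on the 2x2 table.  Two backgrounds are supported:
the catalog's full annotated universe (MSigDB-style) and an explicit
restricted background such as brain-expressed genes (SynGO-style).  Following
the triple rule used for this analysis, a term counts as significantly
over-represented only when the raw p, the BH-adjusted p, and the q value
(positive-FDR estimate) are all below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import AnnotationCatalog, GeneSet

__all__ = ["ORARecord", "over_representation", "restricted_background_ora", "q_values"]


@dataclass
class ORARecord:
    """Hypergeometric over-representation of one annotation term.

    k of the n foreground genes (after universe intersection) hit the term,
    which covers K of the N universe genes.
    """

    term: str
    k: int
    n: int
    K: int
    N: int
    p: float
    p_adjusted: float = float("nan")
    q: float = float("nan")
    genes: tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return self.p < 0.05 and self.p_adjusted < 0.05 and self.q < 0.05

    @property
    def foreground_ratio(self) -> float:
        return self.k / self.n

    @property
    def background_ratio(self) -> float:
        return self.K / self.N


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n); the one-sided Fisher p."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def q_values(p_values, pi0_lambda: float = 0.5, min_tests_for_pi0: int = 20) -> np.ndarray:
    """Storey-style positive-FDR q values.

    pi0 is estimated as #(p > lambda) / (m (1 - lambda)) at lambda = 0.5,
    capped to (0, 1]; with fewer than ``min_tests_for_pi0`` tests pi0 is fixed
    at 1, in which case q equals the BH-adjusted p.  q_i = pi0 * min_{j: p_j >=
    p_i} (m p_(j) / j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        raise ValueError("empty p-value vector")
    if m < min_tests_for_pi0:
        pi0 = 1.0
    else:
        pi0 = (p > pi0_lambda).sum() / (m * (1.0 - pi0_lambda))
        pi0 = min(1.0, max(pi0, 1.0 / m))
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, pi0 * m * p[idx] / (rank + 1))
        q[idx] = running
    return np.clip(q, 0.0, 1.0)


def _ora_records(
    foreground: frozenset[str],
    catalog: AnnotationCatalog,
    universe: frozenset[str],
    universe_size: int | None = None,
) -> list[ORARecord]:
    fg = foreground & universe
    if not fg:
        raise ValueError("foreground has no genes in the universe")
    if not catalog.terms:
        raise ValueError("annotation catalog is empty")
    N = universe_size if universe_size is not None else len(universe)
    n = len(fg)
    records = []
    for term in sorted(catalog.terms):
        term_genes = catalog.terms[term] & universe
        K = len(term_genes)
        if K == 0:
            continue
        hit = sorted(fg & term_genes)
        k = len(hit)
        records.append(
            ORARecord(term=term, k=k, n=n, K=K, N=N,
                      p=hypergeom_upper_tail(k, N, K, n), genes=tuple(hit))
        )
    if not records:
        raise ValueError("no annotation term intersects the universe")
    p = [r.p for r in records]
    m = len(p)
    # BH-adjusted p: monotone step-up adjustment
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, m * p[idx] / (rank + 1))
        adj[idx] = running
    qs = q_values(p)
    for rec, a, qv in zip(records, adj, qs):
        rec.p_adjusted = float(a)
        rec.q = float(qv)
    return records


def over_representation(
    foreground: GeneSet,
    catalog: AnnotationCatalog,
    universe: GeneSet | None = None,
) -> list[ORARecord]:
    """ORA against the catalog's full annotated universe (MSigDB-style).

    ``universe`` overrides the catalog's annotated-gene union; the reported N
    uses the catalog's declared ``universe_size`` when that is larger than the
    union (a catalog may annotate more genes than its terms enumerate).
    """
    if universe is not None:
        uni = frozenset(universe.members)
        size = len(uni)
    else:
        uni = catalog.annotated_genes()
        size = catalog.universe_size
    return _ora_records(frozenset(foreground.members), catalog, uni, size)


def restricted_background_ora(
    foreground: GeneSet,
    catalog: AnnotationCatalog,
    background: GeneSet,
) -> list[ORARecord]:
    """ORA with an explicit restricted background (SynGO-style).

    The universe becomes the background set: N = |background|, K = |term &
    background|, n = |foreground & background|.  Foreground genes absent from
    the background are excluded from n.
    """
    return _ora_records(
        frozenset(foreground.members), catalog, frozenset(background.members)
    )
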