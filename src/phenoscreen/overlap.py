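"""Set-overlap decompositions and Fisher enrichment between gene sets.

Covers the Venn breakdown of two or three gene sets, the one-sided Fisher
(hypergeometric-tail) test of whether phenotype-correlated members of a GWAS
set are enriched for membership in a reference set (e.g. HAR genes), and the
"genes of interest" rule: screen hits that belong to at least two of the three
input sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import GeneSet
from .screen import GeneScreenRecord

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "venn_counts",
    "overlap_enrichment",
    "genes_of_interest",
]


@dataclass
class ContingencyTable:
    """2x2 counts: rows = in/not-in the subset of interest, columns = member /
    non-member of the reference set."""

    a: int  # subset & reference
    b: int  # subset & not reference
    c: int  # not subset & reference
    d: int  # not subset & not reference

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValueError("contingency counts must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class EnrichmentResult:
    table: ContingencyTable
    odds_ratio: float
    p_one_sided: float
    percent_subset: float
    percent_full: float


def venn_counts(sets: list[GeneSet]) -> dict[str, int]:
    """Disjoint region counts for 2 or 3 gene sets.

    Region keys are sorted '&'-joined set-name combinations (e.g. ``A``,
    ``A&B``, ``A&B&C``); totals per input set are included under
    ``total:<name>`` and the union under ``union``.
    """
    if len(sets) not in (2, 3):
        raise ValueError("venn_counts supports exactly 2 or 3 sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("set names must be distinct")
    universe = set()
    for s in sets:
        universe |= s.members
    regions: dict[str, int] = {}
    for gene in universe:
        key = "&".join(n for n, s in zip(names, sets) if gene in s)
        regions[key] = regions.get(key, 0) + 1
    # make every possible region explicit, including empty ones
    from itertools import combinations

    for k in range(1, len(sets) + 1):
        for combo in combinations(names, k):
            regions.setdefault("&".join(combo), 0)
    out = dict(sorted(regions.items()))
    for s in sets:
        out[f"total:{s.name}"] = len(s)
    out["union"] = len(universe)
    return out


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def overlap_enrichment(
    full_set: GeneSet,
    correlated_subset: GeneSet,
    reference_set: GeneSet,
) -> EnrichmentResult:
    """Is reference-set membership enriched among the correlated members of a set?

    Rows of the 2x2 split ``full_set`` into correlated vs non-correlated genes;
    columns split by membership in ``reference_set``.  The one-sided Fisher
    p (alternative: correlated genes are MORE often reference members) is the
    exact hypergeometric upper tail.  Percentages report
    ``|subset & ref| / |subset|`` and ``|full & ref| / |full|``.
    """
    if not correlated_subset.members <= full_set.members:
        extra = sorted(correlated_subset.members - full_set.members)[:5]
        raise ValueError(f"correlated subset is not contained in the full set; e.g. {extra}")
    sub = correlated_subset.members
    rest = full_set.members - sub
    ref = reference_set.members
    a = len(sub & ref)
    b = len(sub - ref)
    c = len(rest & ref)
    d = len(rest - ref)
    table = ContingencyTable(a, b, c, d)
    _, p = stats.fisher_exact(table.as_array(), alternative="greater")
    return EnrichmentResult(
        table=table,
        odds_ratio=_sample_odds_ratio(a, b, c, d),
        p_one_sided=float(p),
        percent_subset=100.0 * a / len(sub),
        percent_full=100.0 * len(full_set.members & ref) / len(full_set),
    )


def genes_of_interest(
    tdl_records: list[GeneScreenRecord],
    ap_records: list[GeneScreenRecord],
    sets: list[GeneSet],
    min_memberships: int = 2,
) -> frozenset[str]:
    """Screen hits shared by at least two of the three gene sets.

    Takes the union of significant genes over both phenotype screens (run per
    set and pooled by the caller) and keeps the genes belonging to at least
    ``min_memberships`` of the input sets.  May be empty.
    """
    if len(sets) != 3:
        raise ValueError("genes_of_interest expects exactly 3 gene sets")
    hits = {r.gene for r in tdl_records if r.significant}
    hits |= {r.gene for r in ap_records if r.significant}
    out = {
        g for g in hits
        if sum(g in s.members for s in sets) >= min_memberships
    }
    return frozenset(out)
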