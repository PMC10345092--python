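"""Two-level group comparisons for nested (multi-donor) single-cell data.

Cell-level comparisons use the tie-corrected Kruskal-Wallis H with Dunn's
pairwise post-hoc z tests under Holm step-down adjustment.  Donor-level
comparisons collapse each (donor, condition) cell population to its median and
apply the Friedman test on the complete donors x conditions block, treating
donors — not cells — as the statistical units.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairwiseRecord",
    "GroupTestResult",
    "DonorTestResult",
    "kruskal_wallis",
    "dunn_holm",
    "holm_adjust",
    "donor_collapse",
    "friedman",
]


@dataclass
class PairwiseRecord:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float


@dataclass
class GroupTestResult:
    statistic: float
    p: float
    group_ns: dict[str, int]
    posthoc: list[PairwiseRecord] = field(default_factory=list)


@dataclass
class DonorTestResult:
    statistic: float
    p: float
    n_donors: int
    n_conditions: int
    donor_medians: pd.DataFrame
    p_exact: float | None = None


def _split_groups(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    out: dict[str, np.ndarray] = {}
    for g in pd.unique(groups):
        out[str(g)] = values[groups == g]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    return out


def kruskal_wallis(values, groups) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p on k-1 df.

    Identical values across all groups give H = 0, p = 1 (no rank separation)
    rather than an error.
    """
    by_group = _split_groups(values, groups)
    samples = list(by_group.values())
    if all(np.all(s == samples[0][0]) for s in samples):
        return GroupTestResult(0.0, 1.0, {g: len(v) for g, v in by_group.items()})
    h, p = stats.kruskal(*samples)
    return GroupTestResult(float(h), float(p), {g: len(v) for g, v in by_group.items()})


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def dunn_holm(
    values,
    groups,
    reference_groups: list[str] | None = None,
) -> list[PairwiseRecord]:
    """Dunn's pairwise z tests on pooled ranks with Holm adjustment.

    By default every group pair is tested; ``reference_groups`` restricts the
    family to pairs that include at least one of the named groups (the
    vs-reference design some comparisons use).  The z statistic uses the pooled
    average ranks with the standard tie correction:

        z = (Rbar_a - Rbar_b) / sqrt((N(N+1)/12 - T) (1/n_a + 1/n_b)),
        T = sum(t^3 - t) / (12 (N - 1)).
    """
    by_group = _split_groups(values, groups)
    names = list(by_group.keys())
    pooled = np.concatenate([by_group[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)

    mean_ranks: dict[str, float] = {}
    start = 0
    for g in names:
        n = len(by_group[g])
        mean_ranks[g] = float(ranks[start:start + n].mean())
        start += n

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = [
        (a, b)
        for a, b in itertools.combinations(names, 2)
        if reference_groups is None or a in reference_groups or b in reference_groups
    ]
    records = []
    for a, b in pairs:
        denom = math.sqrt(base_var * (1.0 / len(by_group[a]) + 1.0 / len(by_group[b])))
        if denom == 0:  # all pooled values identical
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / denom
            p_raw = 2.0 * stats.norm.sf(abs(z))
        records.append(PairwiseRecord(a, b, float(z), float(p_raw), np.nan))
    adj = holm_adjust([r.p_raw for r in records])
    for rec, pa in zip(records, adj):
        rec.p_adjusted = float(pa)
    return records


def donor_collapse(
    values,
    donor_labels,
    condition_labels,
    statistic: str = "median",
) -> pd.DataFrame:
    """Collapse per-cell values to one summary per (donor, condition).

    Donors missing any condition are dropped (with a warning) rather than
    imputed: the downstream Friedman test needs a complete block design.
    Returns a donors x conditions DataFrame.
    """
    df = pd.DataFrame(
        {"value": np.asarray(values, dtype=float),
         "donor": np.asarray(donor_labels).astype(str),
         "condition": np.asarray(condition_labels).astype(str)}
    )
    agg = {"median": "median", "mean": "mean"}[statistic]
    table = df.pivot_table(index="donor", columns="condition", values="value", aggfunc=agg)
    incomplete = table.index[table.isna().any(axis=1)].tolist()
    if incomplete:
        warnings.warn(f"dropping donors with incomplete conditions: {incomplete}")
        table = table.drop(index=incomplete)
    if len(table) < 2:
        raise ValueError("fewer than 2 donors with complete condition coverage")
    return table


def _friedman_statistic(block: np.ndarray) -> float:
    """Friedman chi-square on an n x k block, average ranks for ties,
    standard tie correction."""
    n, k = block.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, block)
    col_sums = ranks.sum(axis=0)
    chisq = 12.0 / (n * k * (k + 1)) * float((col_sums**2).sum()) - 3.0 * n * (k + 1)
    # tie correction: C = 1 - sum(t^3 - t) / (n k (k^2 - 1))
    ties = 0.0
    for row in block:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    c = 1.0 - ties / (n * k * (k * k - 1))
    if c == 0:
        return 0.0
    return chisq / c


def friedman(donor_medians: pd.DataFrame, exact: bool = False) -> DonorTestResult:
    """Friedman test on a complete donors x conditions matrix.

    The statistic is the (tie-corrected) Friedman chi-square
    ``12/(n k (k+1)) * sum(R_j^2) - 3 n (k+1)`` on within-donor ranks, with an
    asymptotic chi-square p on k-1 df.  With ``exact=True`` and a small design
    (at most ~1e6 within-donor permutations) a permutation p value is computed
    as well, which is preferable for the typical n = 3 donor setting.
    """
    table = pd.DataFrame(donor_medians)
    if table.isna().any().any():
        raise ValueError("donor_medians must be complete (no missing cells)")
    n, k = table.shape
    if n < 2:
        raise ValueError("need at least 2 donors")
    if k < 3:
        raise ValueError("need at least 3 conditions")
    block = table.to_numpy(dtype=float)
    statistic = _friedman_statistic(block)
    p = float(stats.chi2.sf(statistic, k - 1))

    p_exact = None
    if exact:
        n_perm = math.factorial(k) ** n
        if n_perm > 1_000_000:
            raise ValueError(
                f"exact permutation infeasible: {n_perm} within-donor orderings"
            )
        perms = list(itertools.permutations(range(k)))
        count = 0
        for combo in itertools.product(perms, repeat=n):
            permuted = np.stack([block[i, list(combo[i])] for i in range(n)])
            if _friedman_statistic(permuted) >= statistic - 1e-12:
                count += 1
        p_exact = count / n_perm

    return DonorTestResult(float(statistic), p, n, k, table, p_exact)
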