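import numpy as np
import pandas as pd
import pytest

from phenoscreen.io import ExpressionMatrix, GeneSet
from phenoscreen.scoring import cpm_normalize, log_transform


@pytest.fixture
def tiny_counts():
    """4 cells x 5 genes count matrix with one all-zero gene."""
    values = np.array(
        [
            [10, 0, 5, 0, 85],
            [2, 1, 3, 0, 94],
            [0, 0, 8, 0, 92],
            [7, 2, 1, 0, 90],
        ],
        dtype=float,
    )
    return ExpressionMatrix(
        ["c1", "c2", "c3", "c4"], ["g1", "g2", "g3", "g4", "g5"], values, "counts"
    )


@pytest.fixture
def tiny_log(tiny_counts):
    return log_transform(cpm_normalize(tiny_counts))


@pytest.fixture
def metadata():
    return pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3", "c4"],
            "donor_id": ["d1", "d1", "d2", "d2"],
            "area": "MTG",
            "cell_class": "glutamatergic",
            "t_type": ["FREM3", "FREM3", "LTK", "GLP2R"],
            "relative_depth": [0.45, 0.2, 0.1, 0.5],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_kruskal_h(samples):
    """Tie-corrected Kruskal-Wallis H from first principles (explicit ranking)."""
    pooled = np.concatenate(samples)
    n_total = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n_total)
    sorted_vals = pooled[order]
    i = 0
    while i < n_total:
        j = i
        while j < n_total and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average rank, 1-based
        i = j
    h = 0.0
    start = 0
    for s in samples:
        r = ranks[start:start + len(s)]
        h += r.sum() ** 2 / len(s)
        start += len(s)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - ((counts**3 - counts).sum()) / (n_total**3 - n_total)
    return h / correction


def brute_force_hypergeom_tail(k, N, K, n):
    """P(X >= k) by direct summation of hypergeometric terms."""
    from math import comb

    denom = comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            total += comb(K, i) * comb(N - K, n - i)
    return total / denom


def brute_force_bh(p_values, q):
    """BH by scanning every threshold in the sorted p list."""
    p = np.sort(np.asarray(p_values, dtype=float))
    m = len(p)
    critical = 0.0
    for i in range(m, 0, -1):
        if p[i - 1] <= q * i / m:
            critical = p[i - 1]
            break
    flags = np.asarray(p_values) <= critical if critical > 0 else np.zeros(m, bool)
    return critical, flags
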