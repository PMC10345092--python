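"""Per-gene phenotype association screen with Benjamini-Hochberg FDR.

For every retained gene of a set, expression (log10(CPM+1)) is regressed on a
cellular phenotype — total dendritic length or AP rise speed — by ordinary
least squares.  The two-sided p value of the slope equals the Pearson
correlation t test with n-2 degrees of freedom; genes are then flagged by the
BH step-up rule at FDR q, and the critical p (the largest sorted p passing
p_(i) <= i q / m) is reported alongside, as the screen's effective threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .groupstats import GroupTestResult, dunn_holm, kruskal_wallis
from .io import ExpressionMatrix, GeneSet

__all__ = [
    "GeneScreenRecord",
    "FDRResult",
    "HeatmapBundle",
    "per_gene_association",
    "benjamini_hochberg",
    "screen_gene_set",
    "build_heatmap_bundle",
    "correlated_gene_summary",
]


@dataclass
class GeneScreenRecord:
    """Association of one gene's expression with one phenotype."""

    gene: str
    n: int
    slope: float
    r: float
    p: float
    significant: bool = False
    sign: str = ""

    def __post_init__(self) -> None:
        if not self.sign:
            self.sign = "+" if self.r >= 0 else "-"


@dataclass
class FDRResult:
    """Outcome of the BH step-up procedure over one screen."""

    q: float
    m: int
    critical_p: float
    n_significant: int


@dataclass
class HeatmapBundle:
    """Z-scored expression of significant genes, ordered for display.

    Columns (cells) ascend in phenotype (ties broken by cell id); rows (genes)
    ascend in raw screen p.  ``partition`` maps '+'/'-' to the gene lists of
    the positively and negatively correlated panels.
    """

    matrix: np.ndarray
    gene_order: list[str]
    cell_order: list[str]
    phenotype: np.ndarray
    partition: dict[str, list[str]] = field(default_factory=dict)


def _aligned_data(
    matrix: ExpressionMatrix,
    phenotype: pd.DataFrame,
    which: str,
) -> tuple[list[str], np.ndarray]:
    """Cells having both expression and a non-missing value of the phenotype."""
    if which not in ("tdl", "ap_rise_speed"):
        raise ValueError(f"unknown phenotype {which!r}")
    if which not in phenotype.columns:
        raise ValueError(f"phenotype table has no {which!r} column")
    ph = phenotype.set_index("cell_id")[which].dropna()
    cells = [c for c in matrix.cell_ids if c in ph.index]
    if not cells:
        raise ValueError("no cells shared between matrix and phenotype table")
    return cells, ph.loc[cells].to_numpy(dtype=float)


def per_gene_association(
    matrix: ExpressionMatrix,
    phenotype: pd.DataFrame,
    which: str,
    gene_set: GeneSet,
    min_cells: int = 3,
) -> tuple[list[GeneScreenRecord], list[str]]:
    """OLS of each set gene's expression on the phenotype, vectorized.

    Returns (records, dropped) where ``dropped`` lists genes with zero
    expression variance across the screened cells (their correlation is
    undefined).  Cells missing the phenotype are excluded from this screen
    only.
    """
    if matrix.state != "log10cpm1":
        raise ValueError(f"screen expects state='log10cpm1', got {matrix.state!r}")
    cells, y = _aligned_data(matrix, phenotype, which)
    n = len(cells)
    if n < min_cells:
        raise ValueError(f"only {n} cells with both expression and {which}; need >= {min_cells}")
    if np.ptp(y) == 0:
        raise ValueError(f"phenotype {which!r} is constant across the screened cells")

    gidx = matrix.gene_index()
    genes = sorted(g for g in gene_set.members if g in gidx)
    if not genes:
        raise ValueError(f"no genes of set {gene_set.name!r} present in the matrix")
    sub = matrix.subset_cells(cells)
    x = sub.dense()[:, [gidx_g for gidx_g in (sub.gene_index()[g] for g in genes)]]

    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = float(np.sqrt((yc**2).sum()))
    var_ok = sx > 0
    dropped = [g for g, ok in zip(genes, var_ok) if not ok]

    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
        r = np.clip(r, -1.0, 1.0)
        slope = (xc * yc[:, None]).sum(axis=0) / (yc**2).sum()
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(p), 0.0, p)  # |r| == 1 -> t = inf -> p = 0

    records = [
        GeneScreenRecord(gene=g, n=n, slope=float(slope[i]), r=float(r[i]), p=float(p[i]))
        for i, g in enumerate(genes)
        if var_ok[i]
    ]
    return records, dropped


def benjamini_hochberg(p_values, q: float = 0.05) -> tuple[FDRResult, np.ndarray]:
    """BH step-up: find the largest i with p_(i) <= i q / m.

    Returns the FDR summary (critical p is 0 when nothing passes) and a boolean
    flag per input p, significant iff p <= critical_p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.sort(p)
    thresholds = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(order <= thresholds)
    critical_p = float(order[passing[-1]]) if passing.size else 0.0
    flags = p <= critical_p if passing.size else np.zeros(m, dtype=bool)
    return FDRResult(q=q, m=m, critical_p=critical_p, n_significant=int(flags.sum())), flags


def screen_gene_set(
    matrix: ExpressionMatrix,
    phenotype: pd.DataFrame,
    which: str,
    gene_set: GeneSet,
    q: float = 0.05,
) -> tuple[list[GeneScreenRecord], FDRResult, list[str]]:
    """Full screen of one gene set: association + BH flags, convenience wrapper."""
    records, dropped = per_gene_association(matrix, phenotype, which, gene_set)
    fdr, flags = benjamini_hochberg([r.p for r in records], q=q)
    for rec, flag in zip(records, flags):
        rec.significant = bool(flag)
    return records, fdr, dropped


def build_heatmap_bundle(
    matrix: ExpressionMatrix,
    phenotype: pd.DataFrame,
    which: str,
    records: list[GeneScreenRecord],
) -> HeatmapBundle:
    """Z-scored expression of significant genes, cells ranked by phenotype.

    Each gene row is z-scored (population SD) across the screened cells.  Rows
    are ordered by ascending raw p, columns by ascending phenotype with cell-id
    tie-breaks; the '+'/'-' partition mirrors the two heatmap panels
    (positively and negatively correlated genes).
    """
    sig = [r for r in records if r.significant]
    if not sig:
        raise ValueError("no significant genes to display")
    cells, y = _aligned_data(matrix, phenotype, which)
    order = sorted(range(len(cells)), key=lambda i: (y[i], cells[i]))
    cell_order = [cells[i] for i in order]
    y_sorted = y[order]

    sig_sorted = sorted(sig, key=lambda r: (r.p, r.gene))
    gene_order = [r.gene for r in sig_sorted]
    sub = matrix.subset_cells(cell_order).subset_genes(gene_order)
    x = sub.dense().T  # genes x cells
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = (x - mean) / sd
    partition = {
        "+": [r.gene for r in sig_sorted if r.sign == "+"],
        "-": [r.gene for r in sig_sorted if r.sign == "-"],
    }
    return HeatmapBundle(z, gene_order, cell_order, y_sorted, partition)


def correlated_gene_summary(
    matrix: ExpressionMatrix,
    records: list[GeneScreenRecord],
    metadata: pd.DataFrame,
    sign: str,
    group_column: str = "t_type",
    posthoc: bool = True,
) -> tuple[pd.DataFrame, GroupTestResult | None]:
    """Per-cell mean expression of the significant genes of one sign, compared
    across t-types.

    Returns an empty frame (and no test) when no significant gene has the
    requested sign — an allowed outcome, not an error.
    """
    if sign not in ("+", "-"):
        raise ValueError("sign must be '+' or '-'")
    genes = [r.gene for r in records if r.significant and r.sign == sign]
    if not genes:
        return pd.DataFrame(columns=["cell_id", "mean_expression", group_column]), None
    sub = matrix.subset_genes(sorted(genes))
    means = sub.dense().mean(axis=1)
    df = pd.DataFrame({"cell_id": sub.cell_ids, "mean_expression": means})
    df = df.merge(metadata[["cell_id", group_column]], on="cell_id", how="inner")
    result = kruskal_wallis(df["mean_expression"], df[group_column])
    if posthoc and len(df[group_column].unique()) > 2:
        result.posthoc = dunn_holm(df["mean_expression"], df[group_column])
    return df, result
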