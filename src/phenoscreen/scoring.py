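"""Expression normalization, prevalence filtering, and per-cell gene-set scores.

The working scale of the pipeline is log10(CPM+1): each gene's read count is
divided by the cell's total mapped reads, scaled to a million, then
log-transformed.  A gene-set score is the arithmetic mean of that quantity over
the set's retained genes — retained meaning the gene survives the
zero-prevalence filter (expressed in at least 5% of a designated reference
population by default) and is present in the matrix at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet

__all__ = [
    "FilterConfig",
    "PrevalenceReport",
    "cpm_normalize",
    "log_transform",
    "prevalence_filter",
    "gene_set_score",
    "assign_frem3_layer",
]


@dataclass
class FilterConfig:
    """Zero-prevalence filter settings.

    A gene is *excluded* when it has zero expression in strictly more than
    ``zero_fraction_threshold`` of the reference cells (default 0.95, i.e. the
    gene must be detected in at least 5% of reference cells).  ``reference_cells``
    restricts the prevalence computation to a subset (e.g. a smaller Patch-seq
    population applied to a larger survey matrix); ``None`` means all cells.
    """

    zero_fraction_threshold: float = 0.95
    reference_cells: list[str] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.zero_fraction_threshold <= 1):
            raise ValueError("zero_fraction_threshold must be in (0, 1]")


@dataclass
class PrevalenceReport:
    """Bookkeeping from one prevalence_filter run."""

    set_name: str
    n_input: int
    n_retained: int
    excluded_zero_prevalence: list[str] = field(default_factory=list)
    absent_from_matrix: list[str] = field(default_factory=list)
    n_reference_cells: int = 0


def cpm_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert raw counts to counts-per-million per cell.

    ``value[c, g] = counts[c, g] / total_counts[c] * 1e6``.  Cells with zero
    total counts are a hard error (they carry no expression information and
    would divide by zero).
    """
    if matrix.state != "counts":
        raise ValueError(f"cpm_normalize expects state='counts', got {matrix.state!r}")
    dense = matrix.dense()
    totals = dense.sum(axis=1)
    zero_cells = [matrix.cell_ids[i] for i in np.flatnonzero(totals == 0)]
    if zero_cells:
        raise ValueError(f"cells with zero total counts: {zero_cells}")
    values = dense / totals[:, None] * 1e6
    return ExpressionMatrix(list(matrix.cell_ids), list(matrix.gene_ids), values, "cpm")


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log10(CPM + 1)."""
    if matrix.state != "cpm":
        raise ValueError(f"log_transform expects state='cpm', got {matrix.state!r}")
    values = np.log10(matrix.dense() + 1.0)
    return ExpressionMatrix(list(matrix.cell_ids), list(matrix.gene_ids), values, "log10cpm1")


def prevalence_filter(
    matrix: ExpressionMatrix,
    gene_set: GeneSet,
    config: FilterConfig | None = None,
) -> tuple[GeneSet, PrevalenceReport]:
    """Drop set genes with zero expression in more than the threshold fraction
    of reference cells.

    Exclusion uses a strict inequality: with 276 reference cells and threshold
    0.95, a gene zero in 263 cells (263 > 262.2) is excluded while one zero in
    262 cells is retained.  "Zero" is tested on the raw stored value, which is
    preserved across normalization states (0 counts <=> 0 CPM <=> 0 log).
    Genes absent from the matrix are excluded and reported separately.
    """
    config = config or FilterConfig()
    gidx = matrix.gene_index()
    present = sorted(g for g in gene_set.members if g in gidx)
    absent = sorted(g for g in gene_set.members if g not in gidx)
    if not present:
        raise ValueError(
            f"gene set {gene_set.name!r} has no genes in common with the matrix"
        )

    if config.reference_cells is not None:
        cidx = matrix.cell_index()
        missing = [c for c in config.reference_cells if c not in cidx]
        if missing:
            raise ValueError(f"reference cells not in matrix: {missing[:5]}")
        rows = np.array([cidx[c] for c in config.reference_cells])
    else:
        rows = np.arange(matrix.n_cells)
    n_ref = len(rows)

    dense = matrix.dense()
    cols = np.array([gidx[g] for g in present])
    n_zero = (dense[np.ix_(rows, cols)] == 0).sum(axis=0)
    cutoff = config.zero_fraction_threshold * n_ref
    excluded_mask = n_zero > cutoff
    retained = [g for g, ex in zip(present, excluded_mask) if not ex]
    excluded = [g for g, ex in zip(present, excluded_mask) if ex]

    report = PrevalenceReport(
        set_name=gene_set.name,
        n_input=len(gene_set),
        n_retained=len(retained),
        excluded_zero_prevalence=excluded,
        absent_from_matrix=absent,
        n_reference_cells=n_ref,
    )
    if not retained:
        raise ValueError(
            f"every gene of set {gene_set.name!r} was excluded by the prevalence filter"
        )
    return GeneSet(gene_set.name, frozenset(retained), gene_set.description), report


def gene_set_score(matrix: ExpressionMatrix, retained: GeneSet) -> pd.DataFrame:
    """Per-cell mean expression over the retained genes of one set.

    Expects the log10(CPM+1) scale.  Returns a DataFrame with columns
    ``cell_id``, ``set_name``, ``score``, ``n_genes_used``; every cell uses the
    same gene count.  Cells where all retained genes are zero score 0.
    """
    if matrix.state != "log10cpm1":
        raise ValueError(
            f"gene_set_score expects state='log10cpm1', got {matrix.state!r}"
        )
    gidx = matrix.gene_index()
    genes = sorted(g for g in retained.members if g in gidx)
    if not genes:
        raise ValueError(f"no genes of set {retained.name!r} present in the matrix")
    cols = np.array([gidx[g] for g in genes])
    scores = matrix.dense()[:, cols].mean(axis=1)
    return pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "set_name": retained.name,
            "score": scores,
            "n_genes_used": len(genes),
        }
    )


def assign_frem3_layer(
    metadata: pd.DataFrame,
    boundary: float = 0.3,
    t_type: str = "FREM3",
    labels: tuple[str, str] = ("L2 FREM3", "L3 FREM3"),
) -> pd.DataFrame:
    """Split the FREM3 t-type into L2/L3 subtypes by relative cortical depth.

    Cells deeper than ``boundary`` (strictly) become the L3 subtype; cells at
    or above it the L2 subtype (the boundary itself goes to L2 because L3 is
    defined by a strict inequality).  Non-FREM3 rows are untouched.  FREM3
    cells without a recorded depth are a hard error.
    """
    df = metadata.copy()
    mask = df["t_type"] == t_type
    if not mask.any():
        return df
    if "relative_depth" not in df.columns:
        raise ValueError("metadata has no relative_depth column; cannot split FREM3")
    depth = df.loc[mask, "relative_depth"]
    missing = df.loc[mask & depth.reindex(df.index).isna(), "cell_id"].tolist()
    if missing:
        raise ValueError(f"FREM3 cells lacking relative_depth: {missing}")
    l2, l3 = labels
    df.loc[mask, "t_type"] = np.where(depth > boundary, l3, l2)
    return df
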