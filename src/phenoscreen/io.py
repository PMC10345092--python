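"""Readers and writers for every external artifact of the pipeline.

Expression matrices travel either as delimited tables (cells x genes, first
column = cell id, header = gene symbols, optional ``#state=`` directive line)
or as MatrixMarket coordinate triplets with one-name-per-line companion files.
Gene sets and annotation catalogs use GMT or plain lists; metadata and
phenotype tables are delimited with a header.  All parsing is strict: duplicate
identifiers, negative values, and dimension mismatches are hard errors.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "AnnotationCatalog",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_annotation_catalog",
    "read_table",
    "write_table",
    "write_results",
    "validate_cell_metadata",
    "validate_phenotypes",
]

#: valid normalization states of an expression matrix
STATES = ("counts", "cpm", "log10cpm1")

CELL_METADATA_REQUIRED = ("cell_id", "donor_id", "area", "cell_class", "t_type")
CELL_METADATA_OPTIONAL = ("relative_depth",)
PHENOTYPE_REQUIRED = ("cell_id",)
PHENOTYPE_OPTIONAL = ("tdl", "ap_rise_speed")

CELL_CLASSES = ("glutamatergic", "GABAergic", "non-neuronal")


def _find_duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with an explicit normalization state.

    Parameters
    ----------
    cell_ids, gene_ids
        Unique identifiers for rows (cells) and columns (genes).
    values
        Dense ``numpy`` array or ``scipy.sparse`` matrix, shape
        ``(n_cells, n_genes)``, nonnegative.
    state
        One of ``counts``, ``cpm``, ``log10cpm1``.
    """

    cell_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray | sp.spmatrix
    state: str = "counts"

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        dups = _find_duplicates(self.cell_ids)
        if dups:
            raise ValueError(f"duplicate cell identifiers: {dups}")
        dups = _find_duplicates(self.gene_ids)
        if dups:
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if not sp.issparse(self.values):
            self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.min() < 0:
            raise ValueError("expression matrix contains negative values")

    # -- small conveniences ------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def min(self) -> float:
        if sp.issparse(self.values):
            return float(self.values.min()) if self.values.nnz else 0.0
        return float(self.values.min()) if self.values.size else 0.0

    def dense(self) -> np.ndarray:
        """Dense ``(n_cells, n_genes)`` float array of the values."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def cell_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.cell_ids)}

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.cell_index()
        missing = [c for c in cell_ids if c not in idx]
        if missing:
            raise KeyError(f"cells not in matrix: {missing[:5]}")
        rows = [idx[c] for c in cell_ids]
        vals = self.values[rows, :] if not sp.issparse(self.values) else self.values.tocsr()[rows, :]
        return ExpressionMatrix(list(cell_ids), list(self.gene_ids), vals, self.state)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        cols = [idx[g] for g in gene_ids]
        vals = self.values[:, cols] if not sp.issparse(self.values) else self.values.tocsc()[:, cols]
        return ExpressionMatrix(list(self.cell_ids), list(gene_ids), vals, self.state)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (case-sensitive after whitespace trimming)."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(str(m) for m in self.members))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclass
class AnnotationCatalog:
    """GO-style annotation: term name -> gene symbols, plus the universe size.

    ``universe_size`` defaults to the size of the union of all term sets but
    may be larger when the catalog's source declares a bigger annotated
    universe.
    """

    terms: dict[str, frozenset[str]]
    universe_size: int | None = None

    def __post_init__(self) -> None:
        self.terms = {str(t): frozenset(g) for t, g in self.terms.items()}
        for t, genes in self.terms.items():
            if not genes:
                raise ValueError(f"annotation term {t!r} has an empty gene set")
        union = self.annotated_genes()
        if self.universe_size is None:
            self.universe_size = len(union)
        elif self.universe_size < len(union):
            raise ValueError(
                f"universe_size {self.universe_size} smaller than the union of "
                f"all term sets ({len(union)})"
            )

    def annotated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _infer_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def _companion_paths(path: Path) -> tuple[Path, Path]:
    return path.with_suffix(path.suffix + ".rows"), path.with_suffix(path.suffix + ".cols")


def read_expression_matrix(
    path: str | Path,
    format: str | None = None,
    state: str | None = None,
    orientation: str = "cells_by_genes",
) -> ExpressionMatrix:
    """Read an expression matrix from a delimited table or MatrixMarket triplet.

    The normalization state is taken from an explicit ``state`` argument, a
    ``#state=<state>`` directive on the first line of a delimited file, or
    defaults to ``counts``.  ``orientation`` declares the layout of the file
    (``cells_by_genes`` or ``genes_by_cells``); auto-detection is deliberately
    refused because the square case is ambiguous.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if format is None:
        format = "mtx_triplet" if path.suffix.lower() == ".mtx" else "delimited"

    if format == "delimited":
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline().strip()
        skip = 0
        if first.startswith("#state="):
            directive = first.split("=", 1)[1].strip()
            if state is None:
                state = directive
            skip = 1
        df = pd.read_csv(path, sep=_infer_sep(path), index_col=0, skiprows=skip)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    elif format == "mtx_triplet":
        rows_path, cols_path = _companion_paths(path)
        for p in (rows_path, cols_path):
            if not p.exists():
                raise FileNotFoundError(f"companion name file missing: {p}")
        mat = scipy.io.mmread(str(path)).tocsr()
        row_ids = rows_path.read_text(encoding="utf-8").split()
        col_ids = cols_path.read_text(encoding="utf-8").split()
        if mat.shape != (len(row_ids), len(col_ids)):
            raise ValueError(
                f"triplet dimensions {mat.shape} do not match name files "
                f"({len(row_ids)} rows, {len(col_ids)} cols)"
            )
        values = mat
    else:
        raise ValueError(f"unknown format {format!r}")

    if orientation == "genes_by_cells":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionMatrix(row_ids, col_ids, values, state or "counts")


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, format: str | None = None
) -> Path:
    """Write a matrix as a delimited table (with state directive) or MTX triplet."""
    path = Path(path)
    if format is None:
        format = "mtx_triplet" if path.suffix.lower() == ".mtx" else "delimited"
    if format == "delimited":
        df = pd.DataFrame(matrix.dense(), index=matrix.cell_ids, columns=matrix.gene_ids)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#state={matrix.state}\n")
            df.to_csv(fh, sep=_infer_sep(path), float_format="%.10g", lineterminator="\n")
    elif format == "mtx_triplet":
        rows_path, cols_path = _companion_paths(path)
        scipy.io.mmwrite(str(path), sp.coo_matrix(matrix.values))
        rows_path.write_text("\n".join(matrix.cell_ids) + "\n", encoding="utf-8")
        cols_path.write_text("\n".join(matrix.gene_ids) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------------------
# gene sets and annotations
# ---------------------------------------------------------------------------

def _parse_gmt_line(line: str, lineno: int) -> GeneSet:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated fields, got {len(fields)}")
    name, description = fields[0].strip(), fields[1].strip()
    members: list[str] = []
    n_dup = 0
    for raw in fields[2:]:
        sym = raw.strip()
        if not sym:
            continue
        if sym in members:
            n_dup += 1
        else:
            members.append(sym)
    if not members:
        raise ValueError(f"GMT line {lineno}: set {name!r} has an empty member list")
    if n_dup:
        warnings.warn(f"GMT line {lineno}: dropped {n_dup} duplicate symbol(s) in {name!r}")
    return GeneSet(name, frozenset(members), description)


def read_gene_sets(path: str | Path, format: str | None = None) -> list[GeneSet]:
    """Read gene sets from a GMT file (one set per line) or a plain symbol list.

    A plain list yields a single set named after the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "gmt" if path.suffix.lower() == ".gmt" else "plain_list"
    if format == "gmt":
        sets = []
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                sets.append(_parse_gmt_line(line, lineno))
        return sets
    if format == "plain_list":
        members = [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
        uniq = list(dict.fromkeys(members))
        if len(uniq) < len(members):
            warnings.warn(f"{path.name}: dropped {len(members) - len(uniq)} duplicate symbol(s)")
        return [GeneSet(path.stem, frozenset(uniq))]
    raise ValueError(f"unknown format {format!r}")


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> Path:
    """Write gene sets as GMT (members in sorted order for determinism)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description or "na", *sorted(gs.members)]) + "\n")
    return path


def read_annotation_catalog(
    path: str | Path, universe_size: int | None = None
) -> AnnotationCatalog:
    """Read a GMT file as an annotation catalog (term -> genes)."""
    sets = read_gene_sets(path, format="gmt")
    return AnnotationCatalog({s.name: s.members for s in sets}, universe_size)


# ---------------------------------------------------------------------------
# metadata and phenotype tables
# ---------------------------------------------------------------------------

def validate_cell_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell-metadata table: required columns, unique cells, depth in [0,1]."""
    for col in CELL_METADATA_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"cell metadata is missing required column {col!r}")
    df = df.copy()
    df["cell_id"] = df["cell_id"].astype(str)
    dups = _find_duplicates(list(df["cell_id"]))
    if dups:
        raise ValueError(f"duplicate cell_id in metadata: {dups}")
    if "relative_depth" in df.columns:
        depth = pd.to_numeric(df["relative_depth"], errors="raise")
        bad = df.loc[depth.notna() & ((depth < 0) | (depth > 1)), "cell_id"].tolist()
        if bad:
            raise ValueError(f"relative_depth outside [0,1] for cells: {bad}")
        df["relative_depth"] = depth
    return df


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype table: unique cells, strictly positive values when present."""
    for col in PHENOTYPE_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"phenotype table is missing required column {col!r}")
    df = df.copy()
    df["cell_id"] = df["cell_id"].astype(str)
    dups = _find_duplicates(list(df["cell_id"]))
    if dups:
        raise ValueError(f"duplicate cell_id in phenotype table: {dups}")
    for col in PHENOTYPE_OPTIONAL:
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="raise")
            bad = df.loc[vals.notna() & (vals <= 0), "cell_id"].tolist()
            if bad:
                raise ValueError(f"{col} must be > 0 when present; offending cells: {bad}")
            df[col] = vals
    return df


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a delimited metadata or phenotype table with schema validation.

    ``schema`` is ``cell_metadata`` or ``phenotypes``.  Missing optional values
    are preserved as NaN (absent), never coerced to zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_infer_sep(path))
    try:
        if schema == "cell_metadata":
            return validate_cell_metadata(df)
        if schema == "phenotypes":
            return validate_phenotypes(df)
    except ValueError:
        raise
    raise ValueError(f"unknown schema {schema!r}")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as CSV/TSV with 10-significant-digit floats."""
    path = Path(path)
    df.to_csv(path, sep=_infer_sep(path), index=False, float_format="%.10g",
              lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec):
            rows.append(dataclasses.asdict(rec))
        elif isinstance(rec, Mapping):
            rows.append(dict(rec))
        else:
            raise TypeError(f"cannot serialize record of type {type(rec)}")
    return pd.DataFrame(rows)


def write_results(records, path: str | Path, format: str | None = None) -> Path:
    """Write a collection of result records (dataclasses, dicts, or a DataFrame).

    Column order is deterministic (input order); floats carry 10 significant
    digits; an empty collection yields a header-only file (delimited) or an
    empty JSON list.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "delimited"
    df = _records_to_frame(records)
    if format == "delimited":
        df.to_csv(path, sep=_infer_sep(path), index=False, float_format="%.10g",
                  lineterminator="\n")
    elif format == "json":
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, (frozenset, set)):
                return sorted(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"cannot serialize {type(o)}")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1, default=_default)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
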