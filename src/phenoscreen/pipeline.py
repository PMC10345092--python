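"""End-to-end orchestration: score -> group stats -> screens -> overlap -> ORA.

A single config (YAML or constructed directly) names the input artifacts and
the analysis parameters (prevalence threshold, FDR q, FREM3 depth boundary).
Each stage writes its outputs into the output directory and the run ends with
a manifest listing every artifact with a SHA-256 content hash; a failed stage
aborts with its name, leaves earlier outputs intact, and drops a FAILED
marker.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import groupstats, io, ora, overlap, scoring, screen

log = logging.getLogger("phenoscreen")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    matrix: str
    metadata: str
    phenotypes: str
    gene_sets: str  # GMT with the three sets
    out_dir: str
    annotations: str | None = None  # GMT catalog for ORA
    background: str | None = None  # restricted ORA background (plain list)
    matrix_state: str | None = None
    matrix_orientation: str = "cells_by_genes"
    filter_threshold: float = 0.95
    reference_cells: str | None = None  # optional plain list of cell ids
    fdr_q: float = 0.05
    frem3_boundary: float = 0.3
    reference_set: str = "HAR"  # column set of the overlap enrichment
    group_by: str = "t_type"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _screen_frame(records: list[screen.GeneScreenRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the output manifest (also written to disk).

    Stage order mirrors the analysis narrative: load and normalize, per-set
    scores, group statistics across t-types (cell-level Kruskal-Wallis with
    Dunn-Holm; donor-level Friedman when every donor covers every type), the
    TDL and AP screens per set, the two-of-three genes-of-interest rule, the
    overlap enrichment against the reference set, and optional ORA.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stage = "init"

    def emit(path: Path) -> None:
        artifacts.append(path)

    try:
        # ---- load ----------------------------------------------------------
        stage = "load"
        matrix = io.read_expression_matrix(
            config.matrix, state=config.matrix_state, orientation=config.matrix_orientation
        )
        metadata = io.read_table(config.metadata, "cell_metadata")
        phenotypes = io.read_table(config.phenotypes, "phenotypes")
        gene_sets = io.read_gene_sets(config.gene_sets, format="gmt")
        log.info("loaded %d cells x %d genes, %d gene sets",
                 matrix.n_cells, matrix.n_genes, len(gene_sets))

        # ---- normalize -----------------------------------------------------
        stage = "normalize"
        if matrix.state == "counts":
            matrix = scoring.cpm_normalize(matrix)
        if matrix.state == "cpm":
            matrix = scoring.log_transform(matrix)

        if "relative_depth" in metadata.columns and (metadata["t_type"] == "FREM3").any():
            metadata = scoring.assign_frem3_layer(metadata, boundary=config.frem3_boundary)

        reference_cells = None
        if config.reference_cells:
            reference_cells = [
                ln.strip() for ln in Path(config.reference_cells).read_text().splitlines()
                if ln.strip()
            ]
        fcfg = scoring.FilterConfig(config.filter_threshold, reference_cells)

        # ---- scores + group statistics ------------------------------------
        stage = "score"
        score_frames, retained_sets = [], {}
        filter_rows = []
        for gs in gene_sets:
            retained, report = scoring.prevalence_filter(matrix, gs, fcfg)
            retained_sets[gs.name] = retained
            filter_rows.append(
                {
                    "set_name": gs.name,
                    "n_input": report.n_input,
                    "n_retained": report.n_retained,
                    "n_excluded_zero": len(report.excluded_zero_prevalence),
                    "n_absent": len(report.absent_from_matrix),
                }
            )
            log.info("set %s: retained %d of %d genes", gs.name,
                     report.n_retained, report.n_input)
            score_frames.append(scoring.gene_set_score(matrix, retained))
        scores = pd.concat(score_frames, ignore_index=True)
        emit(io.write_table(scores, out_dir / "scores.tsv"))
        emit(io.write_results(pd.DataFrame(filter_rows), out_dir / "filter_report.tsv"))

        stage = "compare-groups"
        group_results = {}
        merged = scores.merge(metadata, on="cell_id")
        for gs in gene_sets:
            sub = merged[merged["set_name"] == gs.name]
            res = groupstats.kruskal_wallis(sub["score"], sub[config.group_by])
            res.posthoc = groupstats.dunn_holm(sub["score"], sub[config.group_by])
            entry = {
                "kruskal_wallis": {"H": res.statistic, "p": res.p, "group_ns": res.group_ns},
                "dunn_holm": [dataclasses.asdict(r) for r in res.posthoc],
            }
            try:
                medians = groupstats.donor_collapse(
                    sub["score"], sub["donor_id"], sub[config.group_by]
                )
                fr = groupstats.friedman(medians)
                entry["friedman"] = {
                    "statistic": fr.statistic, "p": fr.p,
                    "n_donors": fr.n_donors, "n_conditions": fr.n_conditions,
                }
            except ValueError as exc:
                entry["friedman"] = {"skipped": str(exc)}
            group_results[gs.name] = entry
        path = out_dir / "group_stats.json"
        path.write_text(json.dumps(group_results, indent=1))
        emit(path)

        # ---- phenotype screens --------------------------------------------
        stage = "screen"
        all_records: dict[str, dict[str, list[screen.GeneScreenRecord]]] = {}
        fdr_summary = {}
        for which in ("tdl", "ap_rise_speed"):
            all_records[which] = {}
            for gs in gene_sets:
                records, fdr, dropped = screen.screen_gene_set(
                    matrix, phenotypes, which, retained_sets[gs.name], q=config.fdr_q
                )
                all_records[which][gs.name] = records
                fdr_summary[f"{which}:{gs.name}"] = {
                    **dataclasses.asdict(fdr), "n_dropped_constant": len(dropped),
                }
                log.info("screen %s x %s: %d/%d significant (critical p %.3g)",
                         which, gs.name, fdr.n_significant, fdr.m, fdr.critical_p)
                emit(io.write_results(
                    _screen_frame(records), out_dir / f"screen_{which}_{gs.name}.tsv"
                ))
        path = out_dir / "fdr_summary.json"
        path.write_text(json.dumps(fdr_summary, indent=1))
        emit(path)

        # ---- genes of interest + overlap enrichment -----------------------
        stage = "overlap"
        tdl_pooled = [r for recs in all_records["tdl"].values() for r in recs]
        ap_pooled = [r for recs in all_records["ap_rise_speed"].values() for r in recs]
        goi = overlap.genes_of_interest(tdl_pooled, ap_pooled, gene_sets)
        emit(io.write_table(
            pd.DataFrame({"gene": sorted(goi)}), out_dir / "genes_of_interest.tsv"
        ))

        venn = overlap.venn_counts(gene_sets)
        enrich = {}
        ref_set = next(s for s in gene_sets if s.name == config.reference_set)
        sig_union = {r.gene for r in tdl_pooled + ap_pooled if r.significant}
        for gs in gene_sets:
            if gs.name == config.reference_set:
                continue
            correlated = gs.members & sig_union
            if not correlated:
                enrich[gs.name] = {"skipped": "no correlated genes"}
                continue
            res = overlap.overlap_enrichment(
                gs, io.GeneSet(f"{gs.name}_correlated", frozenset(correlated)), ref_set
            )
            enrich[gs.name] = {
                "table": dataclasses.asdict(res.table),
                "odds_ratio": res.odds_ratio,
                "p_one_sided": res.p_one_sided,
                "percent_subset": res.percent_subset,
                "percent_full": res.percent_full,
            }
        path = out_dir / "overlap_enrichment.json"
        path.write_text(json.dumps({"venn": venn, "enrichment": enrich}, indent=1))
        emit(path)

        # ---- ORA -----------------------------------------------------------
        if config.annotations:
            stage = "ora"
            catalog = io.read_annotation_catalog(config.annotations)
            if goi:
                fg = io.GeneSet("genes_of_interest", frozenset(goi))
                records = ora.over_representation(fg, catalog)
                df = pd.DataFrame(
                    [
                        {
                            "term": r.term, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                            "p": r.p, "p_adjusted": r.p_adjusted, "q": r.q,
                            "significant": r.significant,
                            "genes": ";".join(r.genes),
                        }
                        for r in records
                    ]
                )
                emit(io.write_results(df, out_dir / "ora_full_universe.tsv"))
                if config.background:
                    bg = io.read_gene_sets(config.background)[0]
                    records = ora.restricted_background_ora(fg, catalog, bg)
                    df = pd.DataFrame(
                        [
                            {
                                "term": r.term, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                                "p": r.p, "p_adjusted": r.p_adjusted, "q": r.q,
                                "significant": r.significant,
                                "genes": ";".join(r.genes),
                            }
                            for r in records
                        ]
                    )
                    emit(io.write_results(df, out_dir / "ora_restricted.tsv"))
            else:
                log.info("ORA skipped: empty genes-of-interest list")

    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    stage = "manifest"
    manifest = {
        "config": dataclasses.asdict(config),
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    failed = out_dir / "FAILED"
    if failed.exists():
        failed.unlink()
    return manifest
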