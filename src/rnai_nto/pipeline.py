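"""One seeded, logged run of the full risk-assessment pipeline.

Orchestrates off-target scanning, differential expression, three-class
DEG attribution, enrichment and transcriptome entropy into a single
deterministic invocation that emits the report-shaped artifacts:

    match.tsv         per-gene longest contiguous match with the trigger
    de.tsv            per-gene DE results and change class
    table2_like.tsv   genes binned by match length, with directions
    table1_like.tsv   pathway-proximity level summary
    correlation.tsv   match length vs |log2FC| per matched gene
    enrichment.tsv    hypergeometric over-representation per gene set
    entropy.tsv       per-sample Shannon entropy
    run.log           versions, seed, thresholds, timings, filter counts
    summary.json      machine-readable headline numbers

Separate datasets (e.g. nymph and adult) are separate invocations.
Identical inputs and configuration give byte-identical TSVs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import (
    assign_pathway_levels,
    classify_degs,
    find_homologs,
    summarize_levels,
)
from .de_analysis import nb_wald_test
from .enrichment import enrich
from .entropy import compare_group_entropy
from .io_formats import (
    read_counts,
    read_de_table,
    read_fasta,
    read_gene_sets,
)
from .offtarget_scan import (
    bin_by_match_length,
    match_fold_change_correlation,
    match_results_frame,
    scan_transcriptome,
)
from .reference import IN_PLANTA_DSRNA_NG_PER_G, MAX_HAZARD_FACTOR

__all__ = ["RunConfig", "run_assessment", "maximum_hazard_dose"]

_FLOAT_FMT = "%.10g"


def maximum_hazard_dose(
    in_planta_ng_per_g: float = IN_PLANTA_DSRNA_NG_PER_G,
    factor: float = MAX_HAZARD_FACTOR,
) -> float:
    """Worst-case feeding-test dsRNA concentration (ng/g).

    The animal-feeding test exaggerates exposure by a fixed multiple of
    the concentration the crop expresses in planta (default 100x).
    """
    if in_planta_ng_per_g < 0 or factor <= 0:
        raise ValueError("concentration must be >=0 and factor > 0")
    return in_planta_ng_per_g * factor


@dataclass
class RunConfig:
    """Paths, thresholds and seed of one pipeline invocation."""

    dsrna_fasta: str
    transcriptome_fasta: str
    counts_tsv: str
    groups: dict[str, str]
    out_dir: str
    target_fasta: str | None = None  # defaults to the dsRNA itself
    gene_sets_gmt: str | None = None
    de_table_tsv: str | None = None  # skip the internal DE stage if given
    extra_seed_genes: tuple[str, ...] = ()
    min_match_len: int = 7
    lfc_thresh: float = 1.0
    fdr_thresh: float = 0.05
    boundary: str = "strict"
    evalue_thresh: float = 1e-10
    max_pathway_level: int = 3
    legacy_percent: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("min_match_len", "lfc_thresh", "fdr_thresh", "evalue_thresh",
                     "max_pathway_level"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=_FLOAT_FMT)


def run_assessment(config: RunConfig) -> Path:
    """Run every stage and write the report artifacts; returns the out dir."""
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"rnai_nto {__version__} | numpy {np.__version__} | pandas {pd.__version__}",
        f"seed={config.seed} min_match_len={config.min_match_len} "
        f"lfc_thresh={config.lfc_thresh} fdr_thresh={config.fdr_thresh} "
        f"boundary={config.boundary} evalue_thresh={config.evalue_thresh} "
        f"max_pathway_level={config.max_pathway_level}",
    ]
    summary: dict = {"seed": config.seed}

    dsrna = read_fasta(config.dsrna_fasta)[0]
    transcripts = read_fasta(config.transcriptome_fasta)
    counts = read_counts(config.counts_tsv, config.groups)
    transcript_ids = {t.id for t in transcripts}
    orphans = [g for g in counts.gene_ids if g not in transcript_ids]
    if orphans:
        raise ValueError(
            f"{len(orphans)} count-matrix gene(s) missing from the "
            f"transcriptome FASTA, e.g. {orphans[:10]}"
        )

    # --- off-target scan ---------------------------------------------------
    t = time.perf_counter()
    results = scan_transcriptome(dsrna, transcripts, min_report_len=config.min_match_len)
    _write(match_results_frame(results), out / "match.tsv", "gene")
    n_matched = sum(1 for r in results if not r.below_threshold)
    log_lines.append(
        f"scan: {len(results)} transcripts, {n_matched} with match >= "
        f"{config.min_match_len} [{time.perf_counter() - t:.2f}s]"
    )
    summary["n_transcripts"] = len(results)
    summary["n_matched"] = n_matched

    # --- differential expression -------------------------------------------
    t = time.perf_counter()
    if config.de_table_tsv:
        de = read_de_table(config.de_table_tsv).classify(
            config.lfc_thresh, config.fdr_thresh, config.boundary
        )
        log_lines.append(f"de: imported from {config.de_table_tsv}")
    else:
        de = nb_wald_test(
            counts,
            lfc_thresh=config.lfc_thresh,
            fdr_thresh=config.fdr_thresh,
            boundary=config.boundary,
        )
    _write(de.table, out / "de.tsv", "gene")
    direction = de.direction()
    summary["n_degs"] = len(de.degs())
    summary["n_degs_up"] = int((direction == "up").sum())
    summary["n_degs_down"] = int((direction == "down").sum())
    log_lines.append(
        f"de: {len(de.genes)} genes tested, {summary['n_degs']} DEGs "
        f"({summary['n_degs_up']} up, {summary['n_degs_down']} down) "
        f"[{time.perf_counter() - t:.2f}s]"
    )

    # --- match-length table -------------------------------------------------
    table2 = bin_by_match_length(
        results, de, min_len=config.min_match_len, legacy_percent=config.legacy_percent
    )
    _write(table2, out / "table2_like.tsv", "bin")
    log_lines.append(
        f"table2: {int(table2['total_genes'].sum())} matched genes binned, "
        f"{table2.attrs['n_missing_from_de']} absent from DE counted unchanged"
    )

    # --- homologs + pathway levels ------------------------------------------
    t = time.perf_counter()
    target = (
        read_fasta(config.target_fasta)[0] if config.target_fasta else dsrna
    )
    hits = find_homologs(target, transcripts, evalue_thresh=config.evalue_thresh)
    summary["n_homologs"] = len(hits)
    log_lines.append(
        f"homologs: {len(hits)} hits at E < {config.evalue_thresh} "
        f"[{time.perf_counter() - t:.2f}s]"
    )
    seeds = {h.gene_id for h in hits} | set(config.extra_seed_genes)

    assignment = None
    if config.gene_sets_gmt:
        gene_sets = read_gene_sets(config.gene_sets_gmt)
        if seeds:
            assignment = assign_pathway_levels(
                gene_sets, seeds, max_level=config.max_pathway_level
            )
        else:
            assignment = _empty_assignment()
        table1 = summarize_levels(
            assignment, de, max_level=config.max_pathway_level,
            legacy_percent=config.legacy_percent,
        )
        _write(table1, out / "table1_like.tsv", "level")
        log_lines.append(
            f"table1: {int(table1.loc['Total', 'total_genes'])} pathway-level genes"
        )
    else:
        gene_sets = None
        _write(
            pd.DataFrame(
                columns=["total_genes", "n_up", "n_down", "n_unchanged",
                         "pct_up", "pct_down", "pct_unchanged",
                         "up_cell", "down_cell", "unchanged_cell"]
            ),
            out / "table1_like.tsv", "level",
        )
        log_lines.append("table1: skipped (no gene sets provided)")

    # --- match-length vs fold-change correlation -----------------------------
    try:
        corr, rho, rho_p = match_fold_change_correlation(
            results, de, min_len=config.min_match_len
        )
        summary["spearman_rho"] = rho
        summary["spearman_p"] = rho_p
        _write(corr, out / "correlation.tsv", "gene")
        log_lines.append(f"correlation: rho={rho:.4f} p={rho_p:.3g} over {len(corr)} genes")
    except ValueError as exc:
        _write(
            pd.DataFrame(columns=["max_match", "log2fc", "abs_log2fc", "color_class"]),
            out / "correlation.tsv", "gene",
        )
        summary["spearman_rho"] = None
        log_lines.append(f"correlation: skipped ({exc})")

    # --- enrichment ----------------------------------------------------------
    if gene_sets is not None:
        enr = enrich(de.degs(), set(de.genes), gene_sets)
        _write(enr, out / "enrichment.tsv", "set_name")
        n_sig = int((enr["fdr"] < config.fdr_thresh).sum()) if len(enr) else 0
        summary["n_enriched_sets"] = n_sig
        log_lines.append(f"enrichment: {len(enr)} sets tested, {n_sig} at FDR < "
                         f"{config.fdr_thresh}")
    else:
        _write(
            pd.DataFrame(columns=["k", "K", "n", "N", "fold_enrichment", "pvalue", "fdr"]),
            out / "enrichment.tsv", "set_name",
        )
        log_lines.append("enrichment: skipped (no gene sets provided)")

    # --- DEG attribution ------------------------------------------------------
    deg_classes, class_summary = classify_degs(
        de.degs(), hits, assignment, results, min_match=config.min_match_len
    )
    summary["deg_classes"] = class_summary
    _write(deg_classes, out / "deg_classes.tsv", "gene")

    # --- entropy --------------------------------------------------------------
    ent = compare_group_entropy(counts)
    _write(ent.per_sample, out / "entropy.tsv", "sample")
    summary["entropy"] = {
        "group_means": {g: float(ent.group_stats.loc[g, "mean"]) for g in ent.group_stats.index},
        "group_se": {g: float(ent.group_stats.loc[g, "se"]) for g in ent.group_stats.index},
        "t": ent.t_statistic,
        "p": ent.pvalue,
        "zero_variance": ent.zero_variance,
    }
    log_lines.append(
        f"entropy: t={ent.t_statistic:.3f} p={ent.pvalue:.3g}"
    )

    log_lines.append(f"total runtime {time.perf_counter() - t0:.2f}s")
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def _empty_assignment():
    from .classification import PathwayLevelAssignment

    return PathwayLevelAssignment({}, {}, set())
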