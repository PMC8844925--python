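"""End-to-end orchestration: run the stages in dependency order and emit a
combined per-gene report (expression cluster x operon category x candidate
nomination) plus a machine-readable run manifest.

Intermediate files are the contract between stages — every stage reads and
writes plain text (bedGraph/BED/TSV/GFF3/FASTA), so any stage can be re-run
standalone on the directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import pyfaidx

from . import __version__, expression, genome, integrate, operons, tss

logger = logging.getLogger("capregulon")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run. Every analysis parameter carries
    its standard default and is overridable."""

    gff: str = ""
    fasta: str = ""
    bedgraphs: list[tuple[str, str]] = field(default_factory=list)  # (plus, minus) per replicate
    sams: list[str] = field(default_factory=list)  # alternative to bedgraphs
    counts: str = ""
    metadata: str = ""
    peaks: str = ""
    consensus: str = ""  # IUPAC; empty = skip site scanning
    max_mismatches: int = 2
    outdir: str = "capregulon_out"
    # analysis parameters
    rrs_threshold: float = tss.DEFAULT_RRS_THRESHOLD
    cluster_gap: int = tss.DEFAULT_CLUSTER_GAP
    consensus_min_replicates: int | None = None  # None = all replicates
    assign_window: tuple[int, int] = tss.DEFAULT_ASSIGN_WINDOW
    max_gap: int = operons.DEFAULT_MAX_GAP
    tsc_window: tuple[int, int] = integrate.DEFAULT_TSC_WINDOW
    max_tss_dist: int = integrate.DEFAULT_MAX_TSS_DIST
    fc_up_strong: float = 2.0
    fc_up: float = 1.0
    fc_down: float = -1.0
    alpha: float = 0.05
    pseudocount: float = 1.0
    seed: int = 0
    log_level: str = "INFO"


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns the in-memory results.

    Writes to ``config.outdir``: tss_calls.bed, tss_annotated.tsv,
    operon_categories.tsv, expression_clusters.tsv, candidates.tsv,
    binding_sites.tsv, report.tsv, manifest.json. Any stage failure raises
    :class:`StageError` naming the stage, after removing partial report
    outputs.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "setup"
    t0 = time.time()
    try:
        stage = "annotation"
        annotation = genome.load_annotation(config.gff)
        results["annotation"] = annotation
        logger.info("stage %s done (%.1fs)", stage, time.time() - t0)

        stage = "tss"
        replicate_calls = []
        if config.bedgraphs:
            tracks = [
                tss.read_bedgraph_pair(p, m, replicate_id=f"rep{i + 1}")
                for i, (p, m) in enumerate(config.bedgraphs)
            ]
        elif config.sams:
            tracks = [
                tss.count_read_starts(path, replicate_id=f"rep{i + 1}")
                for i, path in enumerate(config.sams)
            ]
        else:
            raise FileNotFoundError("no 5'-end input (bedgraphs or sams) configured")
        for track in tracks:
            rrs = tss.compute_rrs(track)
            replicate_calls.append(tss.call_tss(rrs, config.rrs_threshold, config.cluster_gap))
        consensus = tss.consensus_tss(
            replicate_calls, tolerance=config.cluster_gap, min_replicates=config.consensus_min_replicates
        )
        reproducible = [c for c in consensus if c.reproducible]
        tss_table = tss.annotate_tss(reproducible, annotation, config.assign_window)
        tss.write_tss_bed(reproducible, str(out / "tss_calls.bed"))
        tss_table.to_csv(out / "tss_annotated.tsv", sep="\t", index=False)
        results["tss_calls"] = reproducible
        results["tss_table"] = tss_table
        logger.info("stage %s done: %d reproducible TSSs (%.1fs)", stage, len(reproducible), time.time() - t0)

        stage = "operons"
        ops = operons.predict_operons(annotation, config.max_gap)
        categories = operons.categorize_genes(ops, tss_table)
        categories.to_csv(out / "operon_categories.tsv", sep="\t", index=False)
        results["operons"] = ops
        results["categories"] = categories
        logger.info("stage %s done: %d units (%.1fs)", stage, len(ops), time.time() - t0)

        stage = "expression"
        if config.counts:
            counts = pd.read_csv(config.counts, sep="\t", index_col=0)
            metadata = pd.read_csv(config.metadata, sep="\t")
            prof = expression.profile_counts(
                counts,
                metadata,
                pseudocount=config.pseudocount,
                thresholds=expression.ClassificationThresholds(
                    config.fc_up_strong, config.fc_up, config.fc_down, config.alpha
                ),
            )
            prof["clusters"].to_csv(out / "expression_clusters.tsv", sep="\t")
            results["expression"] = prof
            logger.info("stage %s done (%.1fs)", stage, time.time() - t0)

        stage = "integrate"
        if config.peaks:
            if not Path(config.peaks).exists():
                raise FileNotFoundError(f"peaks file not found: {config.peaks}")
            peaks = integrate.read_peaks_bed(config.peaks)
            peak_tsc = integrate.peak_to_tsc(peaks, annotation, config.tsc_window)
            peak_tss = integrate.peak_to_tss(peaks, tss_table, config.max_tss_dist)
            candidates = integrate.nominate_candidates(peak_tsc, peak_tss, categories)
            candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
            results["candidates"] = candidates
            if config.consensus and config.fasta:
                fasta = pyfaidx.Fasta(config.fasta)
                site_frames = []
                for gene_id in candidates.loc[candidates["nominated"], "gene_id"]:
                    gene = annotation.get(gene_id)
                    site_frames.append(
                        integrate.scan_promoter(
                            gene,
                            config.assign_window[0],
                            -1,
                            fasta,
                            config.consensus,
                            config.max_mismatches,
                        )
                    )
                sites = (
                    pd.concat(site_frames, ignore_index=True)
                    if site_frames
                    else pd.DataFrame(columns=["gene_id", "center_offset", "matched", "mismatches", "match_strand"])
                )
                sites.to_csv(out / "binding_sites.tsv", sep="\t", index=False)
                results["sites"] = sites
            logger.info("stage %s done (%.1fs)", stage, time.time() - t0)

        stage = "report"
        report = _build_report(results)
        report.to_csv(out / "report.tsv", sep="\t", index=False)
        results["report"] = report

        manifest = {
            "package": "capregulon",
            "version": __version__,
            "seed": config.seed,
            "parameters": {
                k: v
                for k, v in asdict(config).items()
                if k not in ("gff", "fasta", "bedgraphs", "sams", "counts", "metadata", "peaks", "outdir")
            },
            "inputs": {
                name: {"path": path, "sha256": _sha256(path)}
                for name, path in _input_paths(config)
                if path and Path(path).exists()
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        results["manifest"] = manifest
        logger.info("pipeline complete (%.1fs)", time.time() - t0)
        return results
    except Exception as exc:
        for partial in ("report.tsv", "manifest.json"):
            p = out / partial
            if p.exists():
                p.unlink()
        raise StageError(f"stage '{stage}' failed: {exc}") from exc


def _input_paths(config: PipelineConfig):
    yield "gff", config.gff
    yield "fasta", config.fasta
    for i, (p, m) in enumerate(config.bedgraphs):
        yield f"bedgraph_rep{i + 1}_plus", p
        yield f"bedgraph_rep{i + 1}_minus", m
    for i, s in enumerate(config.sams):
        yield f"sam_rep{i + 1}", s
    yield "counts", config.counts
    yield "metadata", config.metadata
    yield "peaks", config.peaks


def _build_report(results: dict) -> pd.DataFrame:
    """One row per gene joining category, expression cluster, TSS evidence,
    and candidate nomination."""
    categories: pd.DataFrame = results["categories"]
    report = categories[["gene_id", "operon_id", "position_in_operon", "category", "has_tss", "tss_ids"]].copy()
    if "expression" in results:
        clusters = results["expression"]["clusters"]
        report = report.merge(
            clusters[["cluster", "deciding_time_h", "deciding_log2fc"]],
            left_on="gene_id",
            right_index=True,
            how="left",
        )
    else:
        report["cluster"] = ""
    if "candidates" in results:
        cand = results["candidates"][
            ["gene_id", "peak_tsc_offset", "min_tss_distance", "criterion1", "criterion2", "nominated"]
        ]
        report = report.merge(cand, on="gene_id", how="left")
        report["nominated"] = report["nominated"].astype("boolean").fillna(False).astype(bool)
    else:
        report["nominated"] = False
    if "sites" in results and len(results["sites"]):
        n_sites = results["sites"].groupby("gene_id").size().rename("n_site_hits")
        report = report.merge(n_sites, on="gene_id", how="left")
        report["n_site_hits"] = report["n_site_hits"].fillna(0).astype(int)
    else:
        report["n_site_hits"] = 0
    return report.sort_values("gene_id").reset_index(drop=True)
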