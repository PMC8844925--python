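"""Operon prediction by intergenic distance and gene categorization.

Adjacent genes on the same strand of a bacterial chromosome that are
separated by at most ``max_gap`` bases (default 50) between the upstream
gene's stop codon and the downstream gene's start codon are chained
transitively into one predicted operon. Each gene is then placed into one of
four transcriptional-unit categories based on operon membership and TSS
evidence: standalone, operon_first, operon_internal, or
operon_internal_with_internal_promoter (an internal gene with its own
assigned TSS, i.e. an internal promoter).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome import Annotation

DEFAULT_MAX_GAP = 50

STANDALONE = "standalone"
OPERON_FIRST = "operon_first"
OPERON_INTERNAL = "operon_internal"
OPERON_INTERNAL_WITH_PROMOTER = "operon_internal_with_internal_promoter"


@dataclass
class Operon:
    """A run of co-transcribed same-strand genes.

    ``gene_ids`` are in transcription order (genomic order on +, reversed on
    −). ``junction_gaps`` has one entry per adjacent pair, in the same order;
    negative values mean the genes overlap. Single genes are represented as
    one-gene operons with no junctions.
    """

    operon_id: str
    chrom: str
    strand: str
    gene_ids: list[str]
    junction_gaps: list[int]

    @property
    def is_singleton(self) -> bool:
        return len(self.gene_ids) == 1


def intergenic_distance(prev_end: int, next_start: int, distance_offset: int = 0) -> int:
    """Bases strictly between two adjacent genes: ``next.start − prev.end − 1``
    so touching genes give 0 and overlapping genes negative values.
    ``distance_offset`` shifts the convention by ±1 if a boundary-inclusive
    definition is preferred."""
    return next_start - prev_end - 1 + distance_offset


def predict_operons(
    annotation: Annotation,
    max_gap: int = DEFAULT_MAX_GAP,
    distance_offset: int = 0,
) -> list[Operon]:
    """Chain adjacent same-strand genes with intergenic distance <= ``max_gap``.

    Adjacency is in genomic order: a gene on the opposite strand between two
    same-strand genes breaks the chain (the flanking neighbour is no longer
    the same-strand gene). Overlapping same-strand genes (negative distance)
    are always chained. Every gene ends up in exactly one operon; singletons
    are returned as one-gene operons.
    """
    operons: list[Operon] = []
    for chrom in annotation.chromosomes:
        genes = annotation.genes_on(chrom)
        run: list = []
        gaps: list[int] = []
        for g in genes:
            if run and g.strand == run[-1].strand:
                d = intergenic_distance(run[-1].end, g.start, distance_offset)
                if d <= max_gap:
                    run.append(g)
                    gaps.append(d)
                    continue
            if run:
                operons.append(_finalize_run(run, gaps, len(operons)))
            run, gaps = [g], []
        if run:
            operons.append(_finalize_run(run, gaps, len(operons)))
    return operons


def _finalize_run(run: list, gaps: list[int], idx: int) -> Operon:
    strand = run[0].strand
    gene_ids = [g.gene_id for g in run]
    if strand == "-":  # transcription order runs right-to-left on the genome
        gene_ids = gene_ids[::-1]
        gaps = gaps[::-1]
    return Operon(
        operon_id=f"operon_{idx:04d}",
        chrom=run[0].chrom,
        strand=strand,
        gene_ids=gene_ids,
        junction_gaps=list(gaps),
    )


def categorize_genes(operons: list[Operon], tss_table: pd.DataFrame) -> pd.DataFrame:
    """Four-way transcriptional-unit category per gene.

    ``tss_table`` is the output of :func:`capregulon.tss.annotate_tss`; a
    gene "has a TSS" when at least one TSS is assigned to it there. Internal
    operon genes with an assigned TSS are upgraded to
    ``operon_internal_with_internal_promoter``.
    """
    assigned = tss_table[tss_table["gene_id"].astype(str) != ""]
    tss_by_gene: dict[str, list[str]] = (
        assigned.groupby("gene_id")["tss_id"].apply(list).to_dict() if len(assigned) else {}
    )
    rows = []
    for op in operons:
        for i, gene_id in enumerate(op.gene_ids):
            tss_ids = tss_by_gene.get(gene_id, [])
            if op.is_singleton:
                category = STANDALONE
            elif i == 0:
                category = OPERON_FIRST
            elif tss_ids:
                category = OPERON_INTERNAL_WITH_PROMOTER
            else:
                category = OPERON_INTERNAL
            rows.append(
                {
                    "gene_id": gene_id,
                    "operon_id": op.operon_id,
                    "position_in_operon": i + 1,
                    "operon_size": len(op.gene_ids),
                    "category": category,
                    "has_tss": bool(tss_ids),
                    "tss_ids": ",".join(tss_ids),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "operon_id", "position_in_operon", "operon_size",
            "category", "has_tss", "tss_ids",
        ],
    )
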