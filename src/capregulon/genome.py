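"""Annotation data model and coordinate conventions.

Coordinates are GFF3-style: 1-based, inclusive on both ends. Positions
relative to a gene's translation start codon (TSC) use the bacterial
promoter-mapping convention: +1 is the first base of the start codon, -1 the
base immediately upstream, and there is **no position 0** (the offset axis has
a one-base discontinuity at the TSC). All offset arithmetic in this package
goes through :func:`genomic_to_tsc_offset` / :func:`tsc_offset_to_genomic` so
that the discontinuity is handled in exactly one place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio.Seq import Seq


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene with strand and 1-based inclusive coordinates.

    ``tsc`` (translation start codon) is the genomic coordinate of the first
    base of the start codon: ``start`` on the + strand, ``end`` on the −
    strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    alias: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: coordinates are 1-based, got start={self.start}")

    @property
    def tsc(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class Annotation:
    """Ordered per-chromosome collection of :class:`GeneRecord`.

    Gene ids are unique; genes are kept sorted by start coordinate within each
    chromosome. ``chrom_lengths`` may be incomplete (lengths are only required
    for sequence extraction and the circular mode).
    """

    def __init__(
        self,
        genes: Iterable[GeneRecord],
        chrom_lengths: Mapping[str, int] | None = None,
    ) -> None:
        self._by_id: dict[str, GeneRecord] = {}
        self._by_chrom: dict[str, list[GeneRecord]] = {}
        for g in genes:
            if g.gene_id in self._by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self._by_id[g.gene_id] = g
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for chrom in self._by_chrom:
            self._by_chrom[chrom].sort(key=lambda g: (g.start, g.end, g.gene_id))
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths or {})

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[GeneRecord]:
        for chrom in sorted(self._by_chrom):
            yield from self._by_chrom[chrom]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def get(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def genes_on(self, chrom: str) -> list[GeneRecord]:
        """Genes on ``chrom`` sorted by start coordinate."""
        return list(self._by_chrom.get(chrom, []))

    def to_frame(self) -> pd.DataFrame:
        """Gene table (one row per gene) exportable as TSV."""
        rows = [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "start": g.start,
                "end": g.end,
                "tsc": g.tsc,
                "alias": g.alias if g.alias is not None else "",
            }
            for g in self
        ]
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end", "tsc", "alias"])


def _parse_gff3_attributes(col: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in col.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def load_annotation(
    path: str,
    feature_types: tuple[str, ...] = ("gene",),
    id_attributes: tuple[str, ...] = ("locus_tag", "ID", "Name", "gene_id"),
    alias_attribute: str = "old_locus_tag",
) -> Annotation:
    """Load gene features from a GFF3 file into an :class:`Annotation`.

    Features whose type is in ``feature_types`` become :class:`GeneRecord`\\ s;
    the gene id is taken from the first attribute key in ``id_attributes``
    that is present. ``##sequence-region`` pragmas populate chromosome
    lengths. Features without a usable strand are rejected with a warning;
    structurally malformed lines raise, naming the offending line.
    """
    genes: list[GeneRecord] = []
    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 tab-separated columns, got {len(fields)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attr_col = fields
            if ftype not in feature_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            attrs = _parse_gff3_attributes(attr_col)
            gene_id = next((attrs[k] for k in id_attributes if k in attrs), None)
            if gene_id is None:
                raise ValueError(f"{path}: line {lineno}: no usable id attribute (tried {id_attributes})")
            if strand not in ("+", "-"):
                warnings.warn(f"{path}: line {lineno}: gene {gene_id!r} without strand, skipped")
                continue
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    alias=attrs.get(alias_attribute),
                )
            )
    return Annotation(genes, chrom_lengths)


def write_annotation_gff3(annotation: Annotation, path: str) -> None:
    """Write gene features (and sequence-region pragmas) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in sorted(annotation.chrom_lengths.items()):
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in annotation:
            attrs = f"ID={g.gene_id};locus_tag={g.gene_id}"
            if g.alias:
                attrs += f";old_locus_tag={g.alias}"
            fh.write(f"{g.chrom}\tcapregulon\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# TSC-relative offsets
# ---------------------------------------------------------------------------


def genomic_to_tsc_offset(pos: int, gene: GeneRecord) -> int:
    """Signed offset of genomic position ``pos`` relative to ``gene``'s TSC.

    +1 is the first base of the start codon; upstream bases are negative;
    there is no offset 0.
    """
    tsc = gene.tsc
    if gene.strand == "+":
        return pos - tsc + 1 if pos >= tsc else pos - tsc
    return tsc - pos + 1 if pos <= tsc else tsc - pos


def tsc_offset_to_genomic(offset: int, gene: GeneRecord) -> int:
    """Inverse of :func:`genomic_to_tsc_offset`. ``offset`` must be nonzero."""
    if offset == 0:
        raise ValueError("TSC-relative offsets have no position 0")
    tsc = gene.tsc
    if gene.strand == "+":
        return tsc + offset - 1 if offset > 0 else tsc + offset
    return tsc - offset + 1 if offset > 0 else tsc - offset


def advance_offset(offset: int, delta: int) -> int:
    """Move ``delta`` bases downstream (coding-strand direction) along the
    offset axis, skipping the missing 0."""
    if offset == 0:
        raise ValueError("TSC-relative offsets have no position 0")
    raw = offset + delta
    if offset < 0 and raw >= 0:
        raw += 1
    elif offset > 0 and raw <= 0:
        raw -= 1
    return raw


def offset_span(from_offset: int, to_offset: int) -> int:
    """Number of bases in the inclusive offset range, accounting for the
    missing 0 when the range straddles the TSC."""
    if from_offset == 0 or to_offset == 0:
        raise ValueError("TSC-relative offsets have no position 0")
    if from_offset > to_offset:
        raise ValueError("from_offset must be upstream of (smaller than) to_offset")
    span = to_offset - from_offset + 1
    if from_offset < 0 < to_offset:
        span -= 1
    return span


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------


def _fetch_slice(genome, chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice from a pyfaidx.Fasta-like or plain-dict genome."""
    seq = genome[chrom]
    if hasattr(seq, "__getitem__") and not isinstance(seq, str):
        # pyfaidx.FastaRecord supports python slicing (0-based half-open)
        return str(seq[start - 1 : end])
    return str(seq)[start - 1 : end]


def extract_promoter_sequence(
    gene: GeneRecord,
    from_offset: int,
    to_offset: int,
    genome,
    chrom_length: int | None = None,
) -> str:
    """Extract the sequence between two TSC-relative offsets, 5'→3' on the
    gene's coding strand.

    ``genome`` is a ``pyfaidx.Fasta`` (or any mapping of chromosome name to
    sequence string). The returned length equals
    ``offset_span(from_offset, to_offset)``.
    """
    span = offset_span(from_offset, to_offset)  # validates ordering/zero
    g_from = tsc_offset_to_genomic(from_offset, gene)
    g_to = tsc_offset_to_genomic(to_offset, gene)
    lo, hi = min(g_from, g_to), max(g_from, g_to)
    if lo < 1:
        raise ValueError(f"region start {lo} lies before the chromosome start")
    if chrom_length is not None and hi > chrom_length:
        raise ValueError(f"region end {hi} lies beyond the chromosome end ({chrom_length})")
    raw = _fetch_slice(genome, gene.chrom, lo, hi)
    if len(raw) != span:
        raise ValueError(f"region {lo}-{hi} lies beyond the end of {gene.chrom}")
    if gene.strand == "-":
        raw = str(Seq(raw).reverse_complement())
    return raw.upper()


# ---------------------------------------------------------------------------
# Strand-symmetry transform (mirror view), used by property tests downstream
# ---------------------------------------------------------------------------


def mirror_position(pos: int, chrom_length: int) -> int:
    """Position of ``pos`` after reverse-complementing a chromosome."""
    return chrom_length - pos + 1


def mirror_gene(gene: GeneRecord, chrom_length: int) -> GeneRecord:
    """Gene record after reverse-complementing its chromosome: coordinates
    mirrored, strand flipped. TSC-relative offsets of any mirrored feature
    are invariant under this transform."""
    return GeneRecord(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand="-" if gene.strand == "+" else "+",
        start=mirror_position(gene.end, chrom_length),
        end=mirror_position(gene.start, chrom_length),
        alias=gene.alias,
    )


def mirror_annotation(annotation: Annotation) -> Annotation:
    """Reverse-complement view of every chromosome in the annotation.

    Requires chromosome lengths for every chromosome carrying genes.
    """
    genes = [mirror_gene(g, annotation.chrom_lengths[g.chrom]) for g in annotation]
    return Annotation(genes, annotation.chrom_lengths)
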