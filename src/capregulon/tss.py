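"""TSS calling from 5'-end enrichment (Cappable-seq style) data.

The model: reads from primary-transcript-enriched libraries start at the
transcription start site, so the genomic coordinate of the first transcribed
base of each mapped read is a TSS vote. Votes are counted per (chromosome,
strand, position) with fractional weights for multi-mapping reads (a read
with k equally best alignments contributes 1/k at each), normalized to a
relative read score RRS = (Rns / Rt) x 1e6 where Rt is the total number of
mapped reads, thresholded (default RRS >= 1.5), clustered by single linkage
at <= 3 nt, and each cluster is reported by its highest-scoring ("max")
position — the major TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import pandas as pd
import pysam

from .genome import Annotation, genomic_to_tsc_offset

DEFAULT_RRS_THRESHOLD = 1.5
DEFAULT_CLUSTER_GAP = 3

Key = tuple[str, str]  # (chrom, strand)


@dataclass
class FivePrimeTrack:
    """Sparse per-(chrom, strand, position) weighted 5'-end read-start counts.

    ``rt`` is the library total: number of reads with at least one best
    alignment (each read counts once, however many places it maps).
    """

    replicate_id: str
    counts: dict[Key, dict[int, float]] = field(default_factory=dict)
    rt: float = 0.0

    def add(self, chrom: str, strand: str, pos: int, weight: float) -> None:
        if weight < 0:
            raise ValueError("read-start weights must be non-negative")
        track = self.counts.setdefault((chrom, strand), {})
        track[pos] = track.get(pos, 0.0) + weight

    def get(self, chrom: str, strand: str, pos: int) -> float:
        return self.counts.get((chrom, strand), {}).get(pos, 0.0)

    def total_weight(self) -> float:
        return sum(sum(d.values()) for d in self.counts.values())


@dataclass
class RrsTrack:
    """Sparse per-position relative read scores for one replicate."""

    replicate_id: str
    scores: dict[Key, dict[int, float]] = field(default_factory=dict)

    def total(self) -> float:
        return sum(sum(d.values()) for d in self.scores.values())


@dataclass
class TssCall:
    """A clustered TSS: member positions passing the threshold, within
    ``cluster_gap`` of each other by single linkage; ``max_position`` is the
    member with the highest RRS (ties broken toward the 5'-most transcribed
    base: smallest coordinate on +, largest on −)."""

    chrom: str
    strand: str
    cluster_start: int
    cluster_end: int
    max_position: int
    max_rrs: dict[str, float]
    members: dict[int, float]
    reproducible: bool | None = None

    @property
    def best_rrs(self) -> float:
        return max(self.max_rrs.values())


# ---------------------------------------------------------------------------
# Counting read starts from alignments
# ---------------------------------------------------------------------------


def _five_prime_position(aln: pysam.AlignedSegment) -> tuple[str, int]:
    """(strand, 1-based genomic coordinate) of the first transcribed base."""
    if aln.is_reverse:
        return "-", aln.reference_end  # reference_end is 0-based exclusive == 1-based last base
    return "+", aln.reference_start + 1


def _alignment_score(aln: pysam.AlignedSegment) -> float | None:
    try:
        return float(aln.get_tag("AS"))
    except KeyError:
        return None


def count_read_starts(alignments, replicate_id: str = "rep") -> FivePrimeTrack:
    """Build a :class:`FivePrimeTrack` from SAM/BAM alignments.

    ``alignments`` is a path to a SAM/BAM file or an iterable of
    ``pysam.AlignedSegment``. For each read, only the equal-best alignments
    (maximal alignment score, ``AS`` tag) are retained and each of the k best
    alignments contributes weight 1/k at its 5'-end position. Reads whose
    alignments carry no score tag fall back to flag-based selection (primary
    alignment treated as best) with a warning. ``rt`` counts reads, not
    alignments.
    """
    if isinstance(alignments, str):
        with pysam.AlignmentFile(alignments, check_sq=False) as fh:
            return count_read_starts(list(fh), replicate_id=replicate_id)

    by_read: dict[str, list[pysam.AlignedSegment]] = {}
    for aln in alignments:
        if aln.is_unmapped:
            continue
        by_read.setdefault(aln.query_name, []).append(aln)

    track = FivePrimeTrack(replicate_id=replicate_id)
    warned = False
    for name, alns in by_read.items():
        scores = [_alignment_score(a) for a in alns]
        if any(s is None for s in scores):
            if not warned and len(alns) > 1:
                warnings.warn("alignments without AS score tags: falling back to flag-based best selection")
                warned = True
            best = [a for a in alns if not a.is_secondary] or alns
        else:
            top = max(scores)
            best = [a for a, s in zip(alns, scores) if s == top]
        w = 1.0 / len(best)
        for aln in best:
            strand, pos = _five_prime_position(aln)
            track.add(aln.reference_name, strand, pos, w)
        track.rt += 1.0
    return track


# ---------------------------------------------------------------------------
# bedGraph I/O (weighted 5'-end counts, one file per strand)
# ---------------------------------------------------------------------------


def write_bedgraph_pair(track: FivePrimeTrack, plus_path: str, minus_path: str) -> None:
    """Write per-strand bedGraph files of the weighted 5'-end counts.

    bedGraph is 0-based half-open; internal positions are 1-based. A
    ``#rt=`` header comment carries the library total so that round-trips
    preserve Rt even when the track is a filtered subset.
    """
    for strand, path in (("+", plus_path), ("-", minus_path)):
        with open(path, "w") as fh:
            fh.write(f"#rt={track.rt!r}\n")
            for (chrom, s), positions in sorted(track.counts.items()):
                if s != strand:
                    continue
                for pos in sorted(positions):
                    fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{positions[pos]!r}\n")


def read_bedgraph_pair(plus_path: str, minus_path: str, replicate_id: str = "rep") -> FivePrimeTrack:
    """Read a per-strand bedGraph pair written by :func:`write_bedgraph_pair`
    (or any bedGraph of per-base 5'-end counts).

    If no ``#rt=`` header is present, Rt defaults to the total weight in the
    two files (exact when every mapped read is represented).
    """
    track = FivePrimeTrack(replicate_id=replicate_id)
    rt_header: float | None = None
    for strand, path in (("+", plus_path), ("-", minus_path)):
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if line.startswith("#rt="):
                        rt_header = float(line[4:])
                    continue
                if line.startswith(("track", "browser")):
                    continue
                chrom, start, end, value = line.split("\t")
                start_i, end_i = int(start), int(end)
                v = float(value)
                # expand multi-base intervals into per-base counts
                for pos in range(start_i + 1, end_i + 1):
                    track.add(chrom, strand, pos, v)
    track.rt = rt_header if rt_header is not None else track.total_weight()
    return track


# ---------------------------------------------------------------------------
# RRS normalization, thresholding, clustering
# ---------------------------------------------------------------------------


def compute_rrs(track: FivePrimeTrack) -> RrsTrack:
    """RRS(pos) = Rns(pos) / Rt x 1e6 for every position with Rns > 0."""
    if track.rt <= 0:
        raise ValueError("Rt must be positive to compute RRS")
    scale = 1e6 / track.rt
    scores = {
        key: {pos: w * scale for pos, w in positions.items() if w > 0}
        for key, positions in track.counts.items()
    }
    return RrsTrack(replicate_id=track.replicate_id, scores={k: v for k, v in scores.items() if v})


def call_tss(
    rrs: RrsTrack,
    threshold: float = DEFAULT_RRS_THRESHOLD,
    cluster_gap: int = DEFAULT_CLUSTER_GAP,
) -> list[TssCall]:
    """Threshold and cluster an RRS track into TSS calls for one replicate.

    Positions with RRS >= ``threshold`` are retained (strictly-below are
    discarded); per strand, retained positions are partitioned by single
    linkage with inter-position distance <= ``cluster_gap``, so flanking
    clusters merge transitively into one large cluster.
    """
    calls: list[TssCall] = []
    for (chrom, strand), positions in sorted(rrs.scores.items()):
        kept = sorted((p, v) for p, v in positions.items() if v >= threshold)
        if not kept:
            continue
        cluster: list[tuple[int, float]] = [kept[0]]
        for p, v in kept[1:]:
            if p - cluster[-1][0] <= cluster_gap:
                cluster.append((p, v))
            else:
                calls.append(_make_call(chrom, strand, cluster, rrs.replicate_id))
                cluster = [(p, v)]
        calls.append(_make_call(chrom, strand, cluster, rrs.replicate_id))
    return calls


def _make_call(chrom: str, strand: str, members: list[tuple[int, float]], rep: str) -> TssCall:
    best = max(v for _, v in members)
    candidates = [p for p, v in members if v == best]
    max_pos = min(candidates) if strand == "+" else max(candidates)
    return TssCall(
        chrom=chrom,
        strand=strand,
        cluster_start=members[0][0],
        cluster_end=members[-1][0],
        max_position=max_pos,
        max_rrs={rep: best},
        members=dict(members),
    )


# ---------------------------------------------------------------------------
# Replicate consensus
# ---------------------------------------------------------------------------


def consensus_tss(
    replicates: list[list[TssCall]],
    tolerance: int = DEFAULT_CLUSTER_GAP,
    min_replicates: int | None = None,
) -> list[TssCall]:
    """Match TSS calls across replicates and flag reproducibility.

    A consensus TSS is emitted where ``min_replicates`` replicates (default:
    all) have a call whose max positions are pairwise within ``tolerance``
    bp; the consensus takes the coordinates of the replicate with the highest
    max RRS and pools the per-replicate scores. Calls without a match are
    retained with ``reproducible=False``.
    """
    if len(replicates) < 2:
        warnings.warn("consensus_tss with <2 replicates: passing calls through unmatched")
        return [replace(c, reproducible=False) for rep in replicates for c in rep]
    need = len(replicates) if min_replicates is None else max(2, min_replicates)

    used: list[set[int]] = [set() for _ in replicates]
    out: list[TssCall] = []
    # seed matches from every replicate so that calls present in (say) reps
    # 2..n but not rep 1 can still satisfy an m-of-n rule
    for i, rep_calls in enumerate(replicates):
        for j, call in enumerate(rep_calls):
            if j in used[i]:
                continue
            group: list[tuple[int, int, TssCall]] = [(i, j, call)]
            for k in range(len(replicates)):
                if k == i:
                    continue
                best_match: tuple[int, TssCall] | None = None
                for m, other in enumerate(replicates[k]):
                    if m in used[k]:
                        continue
                    if other.chrom != call.chrom or other.strand != call.strand:
                        continue
                    if all(abs(other.max_position - g.max_position) <= tolerance for _, _, g in group):
                        d = abs(other.max_position - call.max_position)
                        if best_match is None or d < abs(best_match[1].max_position - call.max_position):
                            best_match = (m, other)
                if best_match is not None:
                    group.append((k, best_match[0], best_match[1]))
            if len(group) >= need:
                for k, m, _ in group:
                    used[k].add(m)
                anchor = max((g for _, _, g in group), key=lambda c: c.best_rrs)
                pooled: dict[str, float] = {}
                for _, _, g in group:
                    pooled.update(g.max_rrs)
                out.append(replace(anchor, max_rrs=pooled, reproducible=True))
    for i, rep_calls in enumerate(replicates):
        for j, call in enumerate(rep_calls):
            if j not in used[i]:
                out.append(replace(call, reproducible=False))
    out.sort(key=lambda c: (c.chrom, c.strand, c.max_position))
    return out


# ---------------------------------------------------------------------------
# Gene assignment
# ---------------------------------------------------------------------------

DEFAULT_ASSIGN_WINDOW = (-500, 100)


def annotate_tss(
    calls: list[TssCall],
    annotation: Annotation,
    assign_window: tuple[int, int] = DEFAULT_ASSIGN_WINDOW,
) -> pd.DataFrame:
    """Assign each TSS to every same-strand gene whose TSC-relative offset of
    the TSS max position falls inside ``assign_window`` (inclusive).

    Returns a long-format table with one row per (TSS, gene) assignment;
    unassigned TSSs get a single row with an empty ``gene_id``.
    """
    lo, hi = assign_window
    rows = []
    for idx, call in enumerate(calls):
        tss_id = f"tss_{idx:05d}"
        assigned = False
        for gene in annotation.genes_on(call.chrom):
            if gene.strand != call.strand:
                continue
            off = genomic_to_tsc_offset(call.max_position, gene)
            if lo <= off <= hi:
                assigned = True
                rows.append(_tss_row(tss_id, call, gene.gene_id, off))
        if not assigned:
            rows.append(_tss_row(tss_id, call, "", None))
    cols = [
        "tss_id", "chrom", "strand", "max_position", "cluster_start", "cluster_end",
        "gene_id", "offset", "max_rrs", "reproducible",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df


def _tss_row(tss_id: str, call: TssCall, gene_id: str, offset: int | None) -> dict:
    return {
        "tss_id": tss_id,
        "chrom": call.chrom,
        "strand": call.strand,
        "max_position": call.max_position,
        "cluster_start": call.cluster_start,
        "cluster_end": call.cluster_end,
        "gene_id": gene_id,
        "offset": offset,
        "max_rrs": call.best_rrs,
        "reproducible": call.reproducible,
    }


def write_tss_bed(calls: list[TssCall], path: str) -> None:
    """BED6 of TSS calls: score = max RRS x 100 rounded, name = cluster id."""
    with open(path, "w") as fh:
        for idx, c in enumerate(calls):
            score = int(round(c.best_rrs * 100))
            fh.write(
                f"{c.chrom}\t{c.max_position - 1}\t{c.max_position}\t"
                f"tss_{idx:05d}\t{score}\t{c.strand}\n"
            )
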