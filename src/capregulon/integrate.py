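"""Regulon integration: nominate direct transcription-factor targets.

A gene (or operon) is nominated as a candidate direct target when a ChIP-seq
peak summit satisfies both promoter criteria:

* criterion 1 — the summit lies within a TSC-relative window (default
  −400..+100 bp, inclusive) of the gene's translation start codon;
* criterion 2 — the summit lies within ``max_dist`` bp (default 200,
  inclusive) of a TSS assigned to the gene.

The module also scans promoter sequences for IUPAC consensus binding sites
with a mismatch budget and computes site-to-TSS distance tables on the
TSC-relative offset axis (accounting for its missing 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .genome import (
    Annotation,
    GeneRecord,
    advance_offset,
    extract_promoter_sequence,
    genomic_to_tsc_offset,
)

DEFAULT_TSC_WINDOW = (-400, 100)
DEFAULT_MAX_TSS_DIST = 200


@dataclass(frozen=True)
class ChipPeak:
    """A ChIP-seq peak summit (single genomic coordinate, 1-based)."""

    chrom: str
    summit: int
    score: float | None = None


def read_peaks_bed(path: str) -> list[ChipPeak]:
    """Read peak summits from BED (0-based half-open).

    Single-base intervals are taken as summits; wider intervals collapse to
    their midpoint with a warning.
    """
    peaks: list[ChipPeak] = []
    warned = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            score = float(fields[4]) if len(fields) > 4 and fields[4] not in (".", "") else None
            if end - start == 1:
                summit = start + 1
            else:
                if not warned:
                    warnings.warn(f"{path}: interval peaks found; using interval midpoints as summits")
                    warned = True
                summit = (start + 1 + end) // 2
            peaks.append(ChipPeak(chrom=chrom, summit=summit, score=score))
    return peaks


def write_peaks_bed(peaks: list[ChipPeak], path: str) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(f"{p.chrom}\t{p.summit - 1}\t{p.summit}\tpeak_{i:04d}\t{score}\t.\n")


# ---------------------------------------------------------------------------
# The two promoter criteria
# ---------------------------------------------------------------------------


def peak_to_tsc(
    peaks: list[ChipPeak],
    annotation: Annotation,
    window: tuple[int, int] = DEFAULT_TSC_WINDOW,
) -> pd.DataFrame:
    """TSC-relative offset of every peak for every gene on its chromosome,
    with criterion-1 flag (offset inside ``window``, inclusive) and, per
    peak, the distance to the closest TSC.

    Only in-window (gene, peak) pairs plus each peak's nearest-TSC row are
    reported, to keep the table sparse.
    """
    lo, hi = window
    rows = []
    for pi, peak in enumerate(peaks):
        genes = annotation.genes_on(peak.chrom)
        if not genes:
            continue
        offsets = [(g, genomic_to_tsc_offset(peak.summit, g)) for g in genes]
        nearest = min(offsets, key=lambda go: abs(peak.summit - go[0].tsc))
        for g, off in offsets:
            in_window = lo <= off <= hi
            if not in_window and g is not nearest[0]:
                continue
            rows.append(
                {
                    "peak_id": f"peak_{pi:04d}",
                    "chrom": peak.chrom,
                    "summit": peak.summit,
                    "gene_id": g.gene_id,
                    "peak_tsc_offset": off,
                    "criterion1": in_window,
                    "nearest_tsc": g is nearest[0],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["peak_id", "chrom", "summit", "gene_id", "peak_tsc_offset", "criterion1", "nearest_tsc"],
    )


def peak_to_tss(
    peaks: list[ChipPeak],
    tss_table: pd.DataFrame,
    max_dist: int = DEFAULT_MAX_TSS_DIST,
) -> pd.DataFrame:
    """Minimum |summit − TSS max position| per (peak, gene) with criterion-2
    flag (distance <= ``max_dist``, inclusive).

    ``tss_table`` is the assignment table from
    :func:`capregulon.tss.annotate_tss`; distances are computed against the
    TSSs assigned to each gene. Genes whose chromosome carries no TSS get
    criterion2 = False with a missing distance.
    """
    assigned = tss_table[tss_table["gene_id"].astype(str) != ""]
    rows = []
    for pi, peak in enumerate(peaks):
        peak_id = f"peak_{pi:04d}"
        sub = assigned[assigned["chrom"] == peak.chrom]
        for gene_id, gene_tss in sub.groupby("gene_id"):
            dists = (gene_tss["max_position"] - peak.summit).abs()
            j = dists.idxmin()
            d = int(dists.loc[j])
            rows.append(
                {
                    "peak_id": peak_id,
                    "gene_id": gene_id,
                    "min_tss_distance": d,
                    "closest_tss_id": gene_tss.loc[j, "tss_id"],
                    "criterion2": d <= max_dist,
                }
            )
    return pd.DataFrame(
        rows, columns=["peak_id", "gene_id", "min_tss_distance", "closest_tss_id", "criterion2"]
    )


def nominate_candidates(
    peak_tsc: pd.DataFrame,
    peak_tss: pd.DataFrame,
    categories: pd.DataFrame,
) -> pd.DataFrame:
    """Combine the two criteria into per-gene candidate calls, with operon
    context.

    A gene is nominated iff some peak satisfies criterion 1 against its TSC
    and criterion 2 against a TSS assigned to it. ``categories`` is the
    output of :func:`capregulon.operons.categorize_genes`. An operon is
    nominated when its first gene or an internal gene with an internal
    promoter is nominated. Output is ranked by minimum peak-TSS distance.
    """
    merged = peak_tsc.merge(peak_tss, on=["peak_id", "gene_id"], how="left")
    merged["criterion2"] = merged["criterion2"].astype("boolean").fillna(False).astype(bool)
    merged["both"] = merged["criterion1"] & merged["criterion2"]

    cat = categories.set_index("gene_id")
    rows = []
    for gene_id, sub in merged.groupby("gene_id"):
        if gene_id not in cat.index:
            continue
        best = sub.sort_values(
            ["both", "criterion1", "min_tss_distance"], ascending=[False, False, True]
        ).iloc[0]
        dist = best["min_tss_distance"]
        rows.append(
            {
                "gene_id": gene_id,
                "operon_id": cat.loc[gene_id, "operon_id"],
                "category": cat.loc[gene_id, "category"],
                "peak_id": best["peak_id"],
                "peak_tsc_offset": int(best["peak_tsc_offset"]),
                "min_tss_distance": int(dist) if pd.notna(dist) else None,
                "criterion1": bool(best["criterion1"]),
                "criterion2": bool(best["criterion2"]),
                "nominated": bool(best["both"]),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "operon_id", "category", "peak_id", "peak_tsc_offset",
            "min_tss_distance", "criterion1", "criterion2", "nominated",
        ],
    )
    if len(df):
        # evidence counts at gene level only when the gene can carry a promoter
        promoter_ok = df["category"].isin(
            ["standalone", "operon_first", "operon_internal_with_internal_promoter"]
        )
        df["operon_nominated"] = False
        op_hit = df.loc[df["nominated"] & promoter_ok, "operon_id"].unique()
        df.loc[df["operon_id"].isin(op_hit), "operon_nominated"] = True
        df = df.sort_values(
            ["nominated", "min_tss_distance"], ascending=[False, True], na_position="last"
        ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Consensus binding-site scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BindingSiteHit:
    """A consensus match inside a scanned promoter sequence.

    ``start`` is the 0-based index of the window in the scanned sequence (on
    the coding strand); ``center_index`` is the left-of-center base for
    even-length consensi. ``strand`` is '+' when the coding-strand sequence
    matches the consensus as given, '−' when its reverse complement does.
    """

    start: int
    center_index: int
    matched: str
    mismatches: int
    strand: str


_IUPAC_ALPHABET = set("ACGTRYSWKMBDHVN")


def _iupac_sets(consensus: str) -> list[set[str]]:
    sets = []
    for ch in consensus.upper():
        if ch not in _IUPAC_ALPHABET:
            raise ValueError(f"invalid IUPAC nucleotide code {ch!r} in consensus")
        sets.append(set(ambiguous_dna_values[ch]))
    return sets


def scan_consensus(sequence: str, consensus: str, max_mismatches: int = 0) -> list[BindingSiteHit]:
    """Slide an IUPAC consensus over both strands of ``sequence`` and report
    windows with at most ``max_mismatches`` mismatching bases (N matches
    everything). Hits are reported in sequence coordinates of the given
    (coding-strand) sequence."""
    seq = sequence.upper()
    m = len(consensus)
    if m > len(seq):
        return []
    fwd = _iupac_sets(consensus)
    rev = _iupac_sets(str(Seq(consensus.upper()).reverse_complement()))
    center = (m - 1) // 2  # left-of-center for even lengths
    hits: list[BindingSiteHit] = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        for strand, sets in (("+", fwd), ("-", rev)):
            mm = sum(1 for b, allowed in zip(window, sets) if b not in allowed)
            if mm <= max_mismatches:
                hits.append(
                    BindingSiteHit(
                        start=i, center_index=i + center, matched=window, mismatches=mm, strand=strand
                    )
                )
    return hits


def scan_promoter(
    gene: GeneRecord,
    from_offset: int,
    to_offset: int,
    genome,
    consensus: str,
    max_mismatches: int = 0,
) -> pd.DataFrame:
    """Scan a gene's promoter window for consensus sites; hit centers are
    reported as TSC-relative offsets."""
    seq = extract_promoter_sequence(gene, from_offset, to_offset, genome)
    hits = scan_consensus(seq, consensus, max_mismatches)
    rows = [
        {
            "gene_id": gene.gene_id,
            "center_offset": advance_offset(from_offset, h.center_index),
            "matched": h.matched,
            "mismatches": h.mismatches,
            "match_strand": h.strand,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "center_offset", "matched", "mismatches", "match_strand"]
    )


# ---------------------------------------------------------------------------
# Site-to-TSS distance arithmetic on the offset axis
# ---------------------------------------------------------------------------


def offset_distance(from_offset: int, to_offset: int) -> int:
    """Signed base-pair distance ``to_offset − from_offset`` on the
    TSC-relative axis, corrected for the missing 0 when the offsets straddle
    the TSC (adjacent bases are always 1 bp apart)."""
    if from_offset == 0 or to_offset == 0:
        raise ValueError("TSC-relative offsets have no position 0")
    d = to_offset - from_offset
    if from_offset * to_offset < 0:
        d -= 1 if d > 0 else -1
    return d


def site_tss_distances(site_center: int, tss_offsets: list[int]) -> pd.DataFrame:
    """Distance from a binding-site center to each TSS (both as TSC-relative
    offsets). Positive values mean the site lies upstream of the TSS."""
    rows = [
        {
            "site_center": site_center,
            "tss_offset": t,
            "distance_bp": offset_distance(site_center, t),
        }
        for t in tss_offsets
    ]
    return pd.DataFrame(rows, columns=["site_center", "tss_offset", "distance_bp"])


def promoter_feature_map(
    gene_id: str,
    tss_offsets: list[int],
    peak_offsets: list[int],
    site_centers: list[int],
) -> pd.DataFrame:
    """Long-format per-gene promoter feature table (TSSs, peak summits and
    binding-site centers on the shared TSC-relative axis) — the tabular
    equivalent of a promoter feature map figure."""
    rows = (
        [{"gene_id": gene_id, "feature": "tss", "offset": o} for o in tss_offsets]
        + [{"gene_id": gene_id, "feature": "peak_summit", "offset": o} for o in peak_offsets]
        + [{"gene_id": gene_id, "feature": "binding_site", "offset": o} for o in site_centers]
    )
    df = pd.DataFrame(rows, columns=["gene_id", "feature", "offset"])
    return df.sort_values("offset", kind="stable").reset_index(drop=True)
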