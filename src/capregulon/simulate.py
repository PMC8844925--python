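"""Seeded synthetic-data generator with planted ground truth.

Generates, at desk scale, the data structures of a bacterial TSS-mapping
study: a random chromosome with planted genes and operons (GFF3 + FASTA),
strand-specific 5'-end read-start tracks with planted TSS pileups for two
biological replicates (bedGraph pairs), a developmental RNA-seq count matrix
over the 0/6/12/18/24 h time course with planted expression-cluster labels,
ChIP-seq peak summits at chosen promoter offsets (BED), and the ground-truth
tables needed to score recovery.

Library scale is chosen so the analysis operates in the regime the RRS
threshold is meant for: with a library total Rt of several million weighted
reads, RRS = 1.5 corresponds to several reads at one position, so single
stray background reads never pass the threshold. Most of the library mass
sits at "housekeeping" promoter pileups (every transcription unit has a
TSS), on top of a low-rate uniform positional background.

The default configuration bundles two reference promoter scenarios: a
dmxB-like first-of-two-gene operon (+ strand) with four planted TSSs at
−297/−213/−171/−135, a ChIP peak at −388 and a consensus binding site
centered at −409; and a pmxA-like last-of-three-gene operon (− strand) with
internal TSSs at −226/−131/−53, an operon-promoter TSS at −63 of its first
gene, and a ChIP peak at −210 — turning those worked promoter coordinates
into end-to-end regression scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genome import (
    Annotation,
    GeneRecord,
    genomic_to_tsc_offset,
    tsc_offset_to_genomic,
    write_annotation_gff3,
)
from .tss import FivePrimeTrack, write_bedgraph_pair

DEFAULT_CONSENSUS = "TGTCANNNNTGACA"


@dataclass
class FocalUnit:
    """A hand-placed transcription unit: (gene_id, length) pairs and
    intergenic gaps in transcription order; strand may be pinned."""

    genes: list[tuple[str, int]]
    gaps: list[int]
    strand: str | None = None


@dataclass
class PlantedTss:
    gene_id: str
    offset: int  # TSC-relative, no 0
    mean_reads: float
    dispersion: float = 0.05
    jitter: int = 0


@dataclass
class PlantedPeak:
    gene_id: str
    offset: int


@dataclass
class PlantedSite:
    gene_id: str
    center_offset: int
    mismatches: int = 0


def _bundled_scenario_units() -> list[FocalUnit]:
    return [
        FocalUnit(genes=[("dmxB_like", 1100), ("dmxB_partner", 900)], gaps=[29], strand="+"),
        FocalUnit(
            genes=[("opx_first", 700), ("opx_mid", 800), ("pmxA_like", 1200)],
            gaps=[20, 35],
            strand="-",
        ),
    ]


def _bundled_scenario_tss() -> list[PlantedTss]:
    return [
        PlantedTss("dmxB_like", -297, 240.0),
        PlantedTss("dmxB_like", -213, 120.0),
        PlantedTss("dmxB_like", -171, 60.0),
        PlantedTss("dmxB_like", -135, 90.0),
        PlantedTss("pmxA_like", -226, 90.0),
        PlantedTss("pmxA_like", -131, 60.0),
        PlantedTss("pmxA_like", -53, 45.0),
        PlantedTss("opx_first", -63, 80.0),
    ]


def _bundled_scenario_peaks() -> list[PlantedPeak]:
    return [PlantedPeak("dmxB_like", -388), PlantedPeak("pmxA_like", -210)]


def _bundled_scenario_sites() -> list[PlantedSite]:
    return [PlantedSite("dmxB_like", -409, 0), PlantedSite("pmxA_like", -195, 1)]


def _bundled_scenario_clusters() -> dict[str, str]:
    return {
        "dmxB_like": "strong_up",
        "pmxA_like": "strong_up",
        "dmxB_partner": "unchanged",
        "opx_first": "unchanged",
        "opx_mid": "unchanged",
    }


@dataclass
class SimulationConfig:
    """Every knob of the generator; identical config + seed gives identical
    output bytes."""

    seed: int = 0
    chrom_name: str = "chr1"
    chrom_length: int = 200_000
    n_background_genes: int = 60
    gene_length_range: tuple[int, int] = (300, 1500)
    operon_fraction: float = 0.3
    operon_size_range: tuple[int, int] = (2, 4)
    intra_gap_range: tuple[int, int] = (0, 50)
    inter_gap_range: tuple[int, int] = (80, 400)
    # 5'-end track generation
    cappable_replicates: int = 2
    housekeeping_offset_range: tuple[int, int] = (-120, -20)
    housekeeping_mean_log: float = np.log(80_000.0)
    housekeeping_mean_sigma: float = 0.5
    tss_dispersion: float = 0.05
    noise_rate: float = 0.2  # expected stray reads per bp per strand
    multimapper_fraction: float = 0.02
    multimapper_k: int = 2
    # RNA-seq count matrix
    time_points: tuple[int, ...] = (0, 6, 12, 18, 24)
    rnaseq_replicates: int = 3
    nb_dispersion: float = 0.05
    base_mean_log: float = np.log(500.0)
    base_mean_sigma: float = 1.0
    min_base_mean: float = 50.0
    # genome-wide label proportions: most genes are developmentally stable,
    # which the median-of-ratios normalization assumes (a focal catalog can
    # be enriched for regulation via planted_clusters)
    cluster_proportions: dict = field(
        default_factory=lambda: {"strong_up": 0.06, "up": 0.10, "down": 0.06, "unchanged": 0.78}
    )
    cluster_effects: dict = field(
        default_factory=lambda: {"strong_up": 4.0, "up": 1.5, "down": -2.0, "unchanged": 0.0}
    )
    size_factor_sigma: float = 0.2
    # planted features
    focal_units: list[FocalUnit] = field(default_factory=_bundled_scenario_units)
    planted_tss: list[PlantedTss] = field(default_factory=_bundled_scenario_tss)
    planted_peaks: list[PlantedPeak] = field(default_factory=_bundled_scenario_peaks)
    planted_sites: list[PlantedSite] = field(default_factory=_bundled_scenario_sites)
    planted_clusters: dict = field(default_factory=_bundled_scenario_clusters)
    site_consensus: str = DEFAULT_CONSENSUS


@dataclass
class TruthTables:
    """Ground truth emitted alongside the synthetic files."""

    operons: list[tuple[str, ...]]
    tss: pd.DataFrame  # gene_id, offset, position, strand, mean_reads, jitter
    clusters: pd.DataFrame  # gene_id, cluster, effect_log2fc, onset_time_h
    candidates: pd.DataFrame  # gene_id, peak offset/position, criterion flags
    sites: pd.DataFrame  # gene_id, center_offset, center_position, mismatches


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------


def gen_genome_annotation(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, Annotation, list[tuple[str, ...]]]:
    """Random chromosome with planted transcription units.

    Returns (sequence, annotation, truth operon gene-id tuples in
    transcription order). Within-unit gaps are <= the operon rule's maximum
    gap; between-unit gaps exceed it, so the truth operons are exactly the
    units recoverable by the distance rule.
    """
    lo_len, hi_len = config.gene_length_range
    units: list[FocalUnit] = [
        FocalUnit(genes=list(u.genes), gaps=list(u.gaps), strand=u.strand)
        for u in config.focal_units
    ]
    remaining = config.n_background_genes
    bi = 0
    while remaining > 0:
        if remaining >= config.operon_size_range[0] and rng.random() < config.operon_fraction:
            size = int(rng.integers(config.operon_size_range[0], config.operon_size_range[1] + 1))
            size = min(size, remaining)
        else:
            size = 1
        genes = []
        for _ in range(size):
            genes.append((f"bg_{bi:04d}", int(rng.integers(lo_len, hi_len + 1))))
            bi += 1
        gaps = [int(rng.integers(*config.intra_gap_range, endpoint=True)) for _ in range(size - 1)]
        units.append(FocalUnit(genes=genes, gaps=gaps, strand=None))
        remaining -= size

    order = rng.permutation(len(units))
    records: list[GeneRecord] = []
    truth_operons: list[tuple[str, ...]] = []
    pos = 1
    for idx in order:
        unit = units[idx]
        pos += int(rng.integers(*config.inter_gap_range, endpoint=True))
        strand = unit.strand or ("+" if rng.random() < 0.5 else "-")
        genes, gaps = unit.genes, unit.gaps
        if strand == "-":  # transcription order runs right-to-left genomically
            genes, gaps = genes[::-1], gaps[::-1]
        for gi, (gene_id, length) in enumerate(genes):
            if gi > 0:
                pos += gaps[gi - 1] + 1
            start = pos
            end = start + length - 1
            records.append(GeneRecord(gene_id=gene_id, chrom=config.chrom_name, strand=strand, start=start, end=end))
            pos = end
        pos += 1
        truth_operons.append(tuple(g for g, _ in unit.genes))
    if pos > config.chrom_length:
        raise ValueError(
            f"planted genes overflow the chromosome ({pos} > {config.chrom_length}); "
            "increase chrom_length or reduce gene count"
        )

    seq = rng.choice(list("ACGT"), size=config.chrom_length)
    annotation = Annotation(records, {config.chrom_name: config.chrom_length})
    _plant_sites(seq, annotation, config, rng)
    return "".join(seq), annotation, truth_operons


def _realize_consensus(consensus: str, n_mismatches: int, rng: np.random.Generator) -> str:
    """A concrete DNA realization of an IUPAC consensus with exactly
    ``n_mismatches`` planted substitutions at informative positions."""
    from Bio.Data.IUPACData import ambiguous_dna_values

    bases = []
    for ch in consensus.upper():
        allowed = ambiguous_dna_values[ch]
        bases.append(allowed[int(rng.integers(len(allowed)))])
    informative = [i for i, ch in enumerate(consensus.upper()) if len(ambiguous_dna_values[ch]) < 4]
    for i in rng.permutation(informative)[:n_mismatches]:
        allowed = set(ambiguous_dna_values[consensus.upper()[i]])
        forbidden = [b for b in "ACGT" if b not in allowed]
        bases[i] = forbidden[int(rng.integers(len(forbidden)))]
    return "".join(bases)


def _plant_sites(
    seq: np.ndarray, annotation: Annotation, config: SimulationConfig, rng: np.random.Generator
) -> None:
    """Overwrite the genome so each planted site matches the consensus (with
    its configured mismatch count) on the gene's coding strand."""
    m = len(config.site_consensus)
    center = (m - 1) // 2
    for site in config.planted_sites:
        gene = annotation.get(site.gene_id)
        realization = _realize_consensus(config.site_consensus, site.mismatches, rng)
        if gene.strand == "-":
            written = str(Seq(realization).reverse_complement())
        else:
            written = realization
        # genomic span of the site window
        from .genome import advance_offset

        start_off = advance_offset(site.center_offset, -center)
        g_positions = sorted(
            tsc_offset_to_genomic(advance_offset(start_off, i), gene) for i in range(m)
        )
        for p, base in zip(g_positions, written):
            seq[p - 1] = base


def write_fasta(sequence: str, chrom_name: str, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom_name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Cappable-seq style 5'-end tracks
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size=None):
    """Negative binomial with variance mean + dispersion * mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def _all_planted_tss(
    config: SimulationConfig,
    annotation: Annotation,
    rng: np.random.Generator,
    promoter_genes: set[str] | None = None,
) -> list[PlantedTss]:
    """Configured focal TSSs plus one housekeeping promoter TSS per gene in
    ``promoter_genes`` (typically the first gene of each transcription unit;
    default: every gene). Drawn once; shared across replicates."""
    planted = list(config.planted_tss)
    explicit = {t.gene_id for t in planted}
    lo, hi = config.housekeeping_offset_range
    for gene in annotation:
        if gene.gene_id in explicit:
            continue
        if promoter_genes is not None and gene.gene_id not in promoter_genes:
            continue
        offset = int(rng.integers(lo, hi + 1))
        if offset == 0:
            offset = -1
        mean = float(np.exp(rng.normal(config.housekeeping_mean_log, config.housekeeping_mean_sigma)))
        planted.append(PlantedTss(gene.gene_id, offset, mean, config.tss_dispersion, 0))
    return planted


def gen_cappable_tracks(
    config: SimulationConfig,
    annotation: Annotation,
    rng: np.random.Generator,
    promoter_genes: set[str] | None = None,
) -> tuple[list[FivePrimeTrack], pd.DataFrame]:
    """Per-replicate weighted 5'-end tracks plus the planted-TSS truth table.

    Replicates share planted positions (pre-jitter) but draw independent
    counts; a configured fraction of each pileup's reads are emitted as
    k-way multimappers (1/k at the true position, 1/k at each of k−1 random
    decoy positions). Uniform background noise is added per strand. Rt is
    the number of simulated reads.
    """
    planted = _all_planted_tss(config, annotation, rng, promoter_genes)
    truth_rows = []
    for t in planted:
        gene = annotation.get(t.gene_id)
        truth_rows.append(
            {
                "gene_id": t.gene_id,
                "offset": t.offset,
                "position": tsc_offset_to_genomic(t.offset, gene),
                "chrom": gene.chrom,
                "strand": gene.strand,
                "mean_reads": t.mean_reads,
                "dispersion": t.dispersion,
                "jitter": t.jitter,
            }
        )
    truth = pd.DataFrame(truth_rows)

    k = config.multimapper_k
    tracks: list[FivePrimeTrack] = []
    for r in range(config.cappable_replicates):
        track = FivePrimeTrack(replicate_id=f"rep{r + 1}")
        for t, row in zip(planted, truth_rows):
            pos = row["position"]
            if t.jitter > 0:
                pos += int(rng.integers(-t.jitter, t.jitter + 1))
            count = int(_nb_draw(rng, t.mean_reads, t.dispersion))
            if count == 0:
                continue
            n_multi = int(round(config.multimapper_fraction * count))
            n_unique = count - n_multi
            key = (row["chrom"], row["strand"])
            if n_unique:
                track.add(*key, pos, float(n_unique))
            if n_multi:
                track.add(*key, pos, n_multi / k)
                decoys = rng.integers(1, config.chrom_length + 1, size=n_multi * (k - 1))
                decoy_strands = rng.random(n_multi * (k - 1)) < 0.5
                for dpos, minus in zip(decoys, decoy_strands):
                    track.add(row["chrom"], "-" if minus else "+", int(dpos), 1.0 / k)
            track.rt += count
        for strand in "+-":
            n_noise = int(rng.poisson(config.noise_rate * config.chrom_length))
            positions = rng.integers(1, config.chrom_length + 1, size=n_noise)
            uniq, counts = np.unique(positions, return_counts=True)
            for p, c in zip(uniq, counts):
                track.add(config.chrom_name, strand, int(p), float(c))
            track.rt += n_noise
        tracks.append(track)
    return tracks, truth


# ---------------------------------------------------------------------------
# RNA-seq count matrix
# ---------------------------------------------------------------------------


def gen_count_matrix(
    config: SimulationConfig, annotation: Annotation, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Counts TSV, sample metadata, and planted cluster-label truth.

    Regulated genes get a constant planted log2 effect from a random onset
    time onward; counts are negative binomial around the time-profile means
    after applying per-sample library-size factors (so normalization is
    exercised).
    """
    genes = [g.gene_id for g in annotation]
    labels = []
    names = list(config.cluster_proportions)
    probs = np.array([config.cluster_proportions[n] for n in names], dtype=float)
    probs /= probs.sum()
    for g in genes:
        if g in config.planted_clusters:
            labels.append(config.planted_clusters[g])
        else:
            labels.append(names[int(rng.choice(len(names), p=probs))])

    times = list(config.time_points)
    reference = times[0]
    # regulation sets in at an intermediate time point and persists, so every
    # regulated gene carries its effect at >= 2 sampled time points
    onset_choices = [t for t in times if t != reference][:-1] or [times[-1]]
    onsets = [int(rng.choice(onset_choices)) for _ in genes]
    base = np.maximum(
        np.exp(rng.normal(config.base_mean_log, config.base_mean_sigma, size=len(genes))),
        config.min_base_mean,
    )

    samples, meta_rows = [], []
    for t in times:
        for rep in range(1, config.rnaseq_replicates + 1):
            name = f"t{t}_r{rep}"
            samples.append((name, t))
            meta_rows.append({"sample": name, "time_h": t, "replicate": rep})
    factors = np.exp(rng.normal(0.0, config.size_factor_sigma, size=len(samples)))

    mat = np.zeros((len(genes), len(samples)), dtype=int)
    truth_rows = []
    for i, (g, label, onset) in enumerate(zip(genes, labels, onsets)):
        effect = config.cluster_effects[label]
        for j, (name, t) in enumerate(samples):
            lfc = effect if (t >= onset and t != reference) else 0.0
            mu = base[i] * (2.0**lfc) * factors[j]
            mat[i, j] = int(_nb_draw(rng, mu, config.nb_dispersion))
        truth_rows.append(
            {"gene_id": g, "cluster": label, "effect_log2fc": effect, "onset_time_h": onset}
        )
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=[s for s, _ in samples])
    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    return counts, metadata, truth


# ---------------------------------------------------------------------------
# ChIP peaks
# ---------------------------------------------------------------------------


def gen_chip_peaks(
    config: SimulationConfig,
    annotation: Annotation,
    tss_truth: pd.DataFrame,
    tsc_window: tuple[int, int] = (-400, 100),
    max_tss_dist: int = 200,
    assign_window: tuple[int, int] = (-500, 100),
) -> tuple[list, pd.DataFrame]:
    """Peak summits at the configured TSC-relative offsets plus the truth
    candidate flags, computed from the planted TSS truth with the two
    promoter criteria."""
    from .integrate import ChipPeak

    peaks, truth_rows = [], []
    for pp in config.planted_peaks:
        gene = annotation.get(pp.gene_id)
        summit = tsc_offset_to_genomic(pp.offset, gene)
        peaks.append(ChipPeak(chrom=gene.chrom, summit=summit))
        criterion1 = tsc_window[0] <= pp.offset <= tsc_window[1]
        assigned = tss_truth[
            (tss_truth["gene_id"] == pp.gene_id)
            & (tss_truth["offset"] >= assign_window[0])
            & (tss_truth["offset"] <= assign_window[1])
        ]
        if len(assigned):
            dist = int((assigned["position"] - summit).abs().min())
            criterion2 = dist <= max_tss_dist
        else:
            dist, criterion2 = None, False
        truth_rows.append(
            {
                "gene_id": pp.gene_id,
                "peak_offset": pp.offset,
                "summit": summit,
                "criterion1": criterion1,
                "criterion2": criterion2,
                "min_tss_distance": dist,
                "nominated": criterion1 and criterion2,
            }
        )
    return peaks, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Bundle: generate everything and write to disk
# ---------------------------------------------------------------------------


def simulate_all(config: SimulationConfig, outdir: str | Path, seed: int | None = None) -> dict:
    """Generate the full synthetic study into ``outdir`` and return the
    in-memory objects plus :class:`TruthTables`.

    Files: genome.fa, annotation.gff3, repN.plus/minus.bedgraph, counts.tsv,
    metadata.tsv, peaks.bed, and truth/*.tsv.
    """
    from .integrate import write_peaks_bed

    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    sequence, annotation, truth_operons = gen_genome_annotation(config, rng)
    first_genes = {unit[0] for unit in truth_operons}
    tracks, tss_truth = gen_cappable_tracks(config, annotation, rng, promoter_genes=first_genes)
    counts, metadata, cluster_truth = gen_count_matrix(config, annotation, rng)
    peaks, candidate_truth = gen_chip_peaks(config, annotation, tss_truth)

    site_rows = []
    for s in config.planted_sites:
        gene = annotation.get(s.gene_id)
        site_rows.append(
            {
                "gene_id": s.gene_id,
                "center_offset": s.center_offset,
                "center_position": tsc_offset_to_genomic(s.center_offset, gene),
                "mismatches": s.mismatches,
            }
        )
    site_truth = pd.DataFrame(site_rows)

    write_fasta(sequence, config.chrom_name, str(out / "genome.fa"))
    write_annotation_gff3(annotation, str(out / "annotation.gff3"))
    for track in tracks:
        write_bedgraph_pair(
            track,
            str(out / f"{track.replicate_id}.plus.bedgraph"),
            str(out / f"{track.replicate_id}.minus.bedgraph"),
        )
    counts.to_csv(out / "counts.tsv", sep="\t")
    metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    write_peaks_bed(peaks, str(out / "peaks.bed"))

    pd.DataFrame({"operon": [";".join(t) for t in truth_operons]}).to_csv(
        out / "truth" / "operons.tsv", sep="\t", index=False
    )
    tss_truth.to_csv(out / "truth" / "tss.tsv", sep="\t", index=False)
    cluster_truth.to_csv(out / "truth" / "clusters.tsv", sep="\t", index=False)
    candidate_truth.to_csv(out / "truth" / "candidates.tsv", sep="\t", index=False)
    site_truth.to_csv(out / "truth" / "sites.tsv", sep="\t", index=False)

    return {
        "sequence": sequence,
        "annotation": annotation,
        "tracks": tracks,
        "counts": counts,
        "metadata": metadata,
        "peaks": peaks,
        "truth": TruthTables(
            operons=truth_operons,
            tss=tss_truth,
            clusters=cluster_truth,
            candidates=candidate_truth,
            sites=site_truth,
        ),
    }
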