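# Methods

This note documents the models, conventions, parameter choices, and known
limitations of `capregulon`, stage by stage.

## Coordinate conventions

All genomic coordinates are GFF3-style, 1-based and inclusive; BED and
bedGraph I/O converts to and from 0-based half-open intervals only at the
file boundary. Positions relative to a gene's translation start codon (TSC)
follow the bacterial promoter-mapping convention: +1 is the first base of
the start codon, −1 the base immediately upstream, and **there is no
position 0**. The offset axis therefore has a one-base discontinuity at the
TSC; `genomic_to_tsc_offset` / `tsc_offset_to_genomic` form an exact
bijection between genomic positions and nonzero offsets, and all interval
lengths and site-to-TSS distances are corrected for the missing 0 so that
adjacent bases are always 1 bp apart. The chromosome is treated as linear;
bacterial chromosomes are circular, but none of the implemented analyses
exercises the origin, so circular wrapping is not applied.

## TSS calling

*Model.* Reads from a primary-transcript-enriched (Cappable-seq style)
library begin at the transcription start site. For each read, only the
alignments sharing the maximal alignment score (`AS` tag) are retained, and
each of the k equal-best alignments contributes weight 1/k at the genomic
coordinate of its first transcribed base (leftmost aligned base on +,
rightmost on −). The per-read weights sum to 1, so the library total
R<sub>t</sub> counts reads, not alignments; a read mapping equally well to
both strands contributes split weight to both tracks. If score tags are
absent, best-hit selection falls back to the primary-alignment flag with a
warning.

*Normalization and thresholding.* RRS = (R<sub>ns</sub>/R<sub>t</sub>) ×
10⁶. The sum of RRS over a complete track is 10⁶ by construction. Positions
with RRS ≥ 1.5 are retained — the comparison is inclusive; strictly-below
positions are discarded before clustering (no cluster-sum thresholding).

*Clustering.* Retained positions on one strand are partitioned by single
linkage with inter-position distance ≤ 3 nt; flanking clusters merge
transitively into one large cluster. Clusters never span strands or
chromosomes. The member with the highest RRS is the major ("max") TSS; when
two members tie exactly, the 5′-most transcribed base wins (smallest
coordinate on +, largest on −) — a deterministic tie-break preferring the
earliest transcribed position.

*Replicate consensus.* A consensus TSS requires a call in every replicate
(configurable to any m of n) with max positions pairwise within the cluster
gap; the consensus takes the coordinates of the replicate with the highest
max RRS and pools per-replicate scores. Unmatched calls are retained,
flagged `reproducible=False`, and excluded from downstream assignment by
the pipeline (only reproducible TSSs feed the operon and candidate stages).

*Gene assignment.* A TSS is assigned to every same-strand gene whose
TSC-relative offset of the max position lies in −500..+100 (inclusive).
The window is deliberately wider upstream than the candidate criterion
window so that distal promoters remain visible in the assignment table.

## Operon mapping

Intergenic distance between genomically adjacent same-strand genes is
`next.start − prev.end − 1`: touching genes give 0, overlapping genes
negative values. Genes with distance ≤ 50 bp are chained transitively;
overlap always chains (overlap is stronger evidence of co-transcription
than a short gap). An intervening opposite-strand gene breaks the chain,
because the flanking neighbour is then not a same-strand gene. The exact
off-by-one convention of "distance between stop and start codons" is
ambiguous in common usage; `distance_offset=±1` shifts it if needed.

Categories: singleton → `standalone`; first gene in transcription order →
`operon_first`; other members → `operon_internal`, upgraded to
`operon_internal_with_internal_promoter` when ≥ 1 TSS is assigned to that
gene. No requirement is placed on the internal TSS lying downstream of the
upstream gene's stop codon — internal promoters of downstream genes
frequently sit inside the upstream gene's coding span, and the assignment
window alone decides.

## Expression profiling

Size factors are classic median-of-ratios: reference genes are those with
nonzero counts in every sample, and each sample's factor is the median
ratio of its counts to the per-gene geometric mean. No rescaling of the
factor vector is applied; consequently multiplying one sample's counts by
c > 0 rescales every normalized column by a common constant c^(1/m) — fold
changes and cluster labels are exactly invariant, absolute normalized
values are not. The estimator assumes most genes are unexpressed-change;
matrices dominated by regulated genes will show attenuated fold changes.

log₂ fold changes use replicate means of normalized counts with a
pseudocount of 1.0 on both numerator and denominator (negligible for counts
≫ 1; configurable). The significance gate is a two-sided Welch t-test on
log₂(normalized + pseudocount) between each time point and the 0 h
reference. This is a location test on log counts and explicitly **not** a
negative-binomial Wald test: it ignores mean–variance modeling and
dispersion shrinkage and is under-powered at n = 2. Externally computed
p-values (e.g. from a dedicated count-model package) can be passed to
`profile_counts(pvalues=...)` for real-data use. With fewer than two
replicates in a group the test returns p = 1. Benjamini–Hochberg adjustment
is applied per time-point contrast by default (`family="global"` pools all
tests).

Classification precedence is `strong_up` (any significant log₂FC ≥ 2) >
`up` (≥ 1) > `down` (≤ −1) > `unchanged`. The down threshold is log₂FC ≤ −1
(two-fold down). A gene significant in both directions is assigned by the
larger |log₂FC| (tie → up) and flagged `mixed`.

## Regulon integration

A peak is its summit coordinate; interval BED records collapse to their
midpoint with a warning. Criterion 1: summit offset within −400..+100 of a
gene's TSC, inclusive at both boundaries. Criterion 2: |summit − TSS max
position| ≤ 200 bp, inclusive, measured against the major TSS (not the
cluster span) of TSSs assigned to the gene. A gene is nominated iff one
peak satisfies both. When a summit falls in the windows of two divergent
genes, both receive independent candidate calls. An operon is flagged
nominated when its first gene or an internal gene with an internal promoter
is nominated.

Consensus scanning slides an IUPAC pattern over both strands of the
promoter sequence; a mismatch is a base outside the IUPAC class at that
position (N matches everything). The center of an even-length consensus is
the left-of-center base, so every reported site center is a single
coordinate.

## Synthetic data generator

The generator emulates the structure of a two-replicate Cappable-seq +
five-time-point (0/6/12/18/24 h) RNA-seq + ChIP-summit study on a single
200 kb chromosome with ~60 background genes at desk scale, with planted
ground truth for every stage:

- **Operons**: background genes are grouped into transcription units
  (operon fraction 0.3, sizes 2–4) with within-unit gaps of 0–50 bp and
  between-unit gaps of 80–400 bp, so the planted units are exactly the ones
  the ≤ 50 bp rule can recover.
- **5′-end tracks**: each transcription unit's first gene carries a
  housekeeping promoter pileup (lognormal mean around 8 × 10⁴ reads);
  focal genes carry configured pileups. Counts are negative binomial with
  variance μ + αμ² (α = 0.05) per replicate; positional jitter is 0 by
  default (single-nucleotide TSSs). Background noise is uniform at 0.2
  reads/bp/strand. The resulting library total (R<sub>t</sub> ≈ 3–4 × 10⁶)
  puts the RRS 1.5 threshold at roughly 5 reads, so isolated stray reads
  cannot create false TSSs — the same qualitative regime in which the
  threshold is used on real libraries. A configured fraction (2%) of each
  pileup's reads are emitted as k-way multimappers (1/k at the true
  position, 1/k at each of k−1 random decoys) as a stress test of the
  fractional weighting, not as a biological repeat model.
- **Count matrix**: 3 replicates per time point (two are typical for real
  studies; three give the stand-in test reasonable power at desk scale).
  Planted effects are +4 (strong_up), +1.5 (up; the midpoint of the [1,2)
  band — an effect of 2 would sit exactly on the strong_up boundary), and
  −2 (down) log₂ units, switching on at a random onset of 6, 12, or 18 h
  and persisting, so every regulated gene carries its effect at ≥ 2 sampled
  time points. Genome-wide label proportions are mostly unchanged
  (6/10/6/78%), as median-of-ratios normalization assumes; the reference
  focal-catalog split (10/18/10/32 of 70) is recorded in
  `capregulon.catalog`. Per-sample library-size factors are lognormal
  (σ = 0.2) so normalization is exercised.
- **Bundled promoter scenarios**: a first-of-two-gene operon on the +
  strand with TSSs at −297/−213/−171/−135, a peak at −388, and an exact
  consensus site centered at −409; and a last-of-three-gene operon on the
  − strand with internal TSSs at −226/−131/−53, an operon-promoter TSS at
  −63 of its first gene, a peak at −210, and a one-mismatch site at −195.
  These turn worked promoter coordinates into end-to-end regression
  fixtures covering both strands.

All generators are pure functions of (config, seed): identical inputs give
byte-identical files. What the generator does **not** emulate: read-level
sequence errors, rRNA contamination, capping-chemistry enrichment
efficiency, fragment-length effects, condition-dependent operon
re-splitting, and genuinely correlated biological replicates. Passing the
recovery tests therefore demonstrates correctness of the inference logic
under the stated noise model, not performance on real libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline on the
default desk-scale study (200 kb, ~65 genes, 2 track replicates,
15 RNA-seq samples), which completes in seconds; oracle comparisons use
200–500 random instances. Floating-point comparisons in tests use relative
tolerances of 1e-9 for algebraic identities and the stated recovery bounds
(TSS recall ≥ 95%, operon recovery 100%, cluster accuracy ≥ 90%, candidate
flags 100%) for stochastic ones. Degenerate inputs: empty RRS tracks yield
empty call lists; R<sub>t</sub> = 0 is an error; zero-variance groups and
single-replicate contrasts return p = 1; genes with a zero count in any
sample are excluded from the size-factor reference set (an all-zeros-prone
matrix raises with a suggestion to use a pseudocount mode).

## Known limitations

- The stand-in differential test is conservative relative to count-model
  tests at small n and does not model NB dispersion.
- TSS classification into primary/secondary/antisense classes beyond gene
  assignment is out of scope, as are peak calling, motif discovery, and
  activation-versus-repression prediction.
- Gene identifiers are carried as a single id plus an optional alias; no
  identifier lift-over is attempted.
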