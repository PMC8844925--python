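"""Promoter criteria, candidate nomination, consensus-site scanning, and
site-to-TSS distance arithmetic."""

import numpy as np
import pandas as pd
import pytest

from capregulon.genome import Annotation, GeneRecord, tsc_offset_to_genomic
from capregulon.integrate import (
    BindingSiteHit,
    ChipPeak,
    nominate_candidates,
    offset_distance,
    peak_to_tsc,
    peak_to_tss,
    promoter_feature_map,
    read_peaks_bed,
    scan_consensus,
    scan_promoter,
    site_tss_distances,
)
from capregulon.operons import categorize_genes, predict_operons

GENE_P = GeneRecord("gp", "c", "+", 5000, 6000)
GENE_M = GeneRecord("gm", "c", "-", 8000, 9000)
ANN = Annotation([GENE_P, GENE_M])


def _peak_at_offset(gene, offset):
    return ChipPeak(chrom=gene.chrom, summit=tsc_offset_to_genomic(offset, gene))


class TestPeakToTsc:
    @pytest.mark.parametrize("offset,expected", [(-388, True), (-400, True), (-401, False), (100, True), (101, False), (-1, True)])
    def test_window_boundaries_inclusive(self, offset, expected):
        df = peak_to_tsc([_peak_at_offset(GENE_P, offset)], ANN)
        row = df[df.gene_id == "gp"].iloc[0]
        assert row.peak_tsc_offset == offset
        assert bool(row.criterion1) is expected

    def test_minus_strand_mirrors_plus(self):
        for off in (-388, -401, 100):
            dp = peak_to_tsc([_peak_at_offset(GENE_P, off)], ANN)
            dm = peak_to_tsc([_peak_at_offset(GENE_M, off)], ANN)
            rp = dp[dp.gene_id == "gp"].iloc[0]
            rm = dm[dm.gene_id == "gm"].iloc[0]
            assert rp.peak_tsc_offset == rm.peak_tsc_offset == off
            assert rp.criterion1 == rm.criterion1

    def test_nearest_tsc_reported_per_peak(self):
        df = peak_to_tsc([ChipPeak("c", 5500)], ANN)
        assert df[df.nearest_tsc].gene_id.tolist() == ["gp"]


def _tss_table(rows):
    cols = ["tss_id", "chrom", "strand", "max_position", "gene_id"]
    return pd.DataFrame(rows, columns=cols)


class TestPeakToTss:
    def test_distance_and_flag(self):
        # summit at -210 and a TSS at -226 relative to the same TSC: 16 bp
        table = _tss_table([("t0", "c", "+", tsc_offset_to_genomic(-226, GENE_P), "gp")])
        df = peak_to_tss([_peak_at_offset(GENE_P, -210)], table)
        assert df.iloc[0].min_tss_distance == 16 and bool(df.iloc[0].criterion2)

    @pytest.mark.parametrize("dist,expected", [(200, True), (201, False), (0, True)])
    def test_boundary_inclusive(self, dist, expected):
        table = _tss_table([("t0", "c", "+", 5000 + dist, "gp")])
        df = peak_to_tss([ChipPeak("c", 5000)], table)
        assert df.iloc[0].min_tss_distance == dist
        assert bool(df.iloc[0].criterion2) is expected

    def test_no_tss_no_rows(self):
        assert len(peak_to_tss([ChipPeak("c", 5000)], _tss_table([]))) == 0


def _categories(ann):
    return categorize_genes(predict_operons(ann), _tss_table([]).assign(gene_id=""))


class TestNominate:
    def _nominate(self, peak_offset, tss_offset):
        peak = _peak_at_offset(GENE_P, peak_offset)
        table = _tss_table([("t0", "c", "+", tsc_offset_to_genomic(tss_offset, GENE_P), "gp")])
        cand = nominate_candidates(peak_to_tsc([peak], ANN), peak_to_tss([peak], table), _categories(ANN))
        return cand.set_index("gene_id").loc["gp"]

    def test_both_criteria_nominates(self):
        row = self._nominate(-388, -297)
        assert row.nominated and row.min_tss_distance == 91

    def test_criterion1_failure_blocks(self):
        row = self._nominate(-450, -460)
        assert not row.nominated and row.criterion2

    def test_criterion2_failure_blocks(self):
        row = self._nominate(-50, -420)
        assert not row.nominated and row.criterion1 and row.min_tss_distance == 370

    def test_monotone_in_windows(self):
        """Enlarging either window never removes a nominated gene."""
        peak = _peak_at_offset(GENE_P, -388)
        table = _tss_table([("t0", "c", "+", tsc_offset_to_genomic(-297, GENE_P), "gp")])
        cats = _categories(ANN)
        base = nominate_candidates(
            peak_to_tsc([peak], ANN, window=(-400, 100)),
            peak_to_tss([peak], table, max_dist=200),
            cats,
        )
        wide = nominate_candidates(
            peak_to_tsc([peak], ANN, window=(-600, 200)),
            peak_to_tss([peak], table, max_dist=400),
            cats,
        )
        nominated_base = set(base[base.nominated].gene_id)
        nominated_wide = set(wide[wide.nominated].gene_id)
        assert nominated_base <= nominated_wide


class TestScanConsensus:
    def test_exact_match(self):
        hits = scan_consensus("AAATGACGTCAAAA", "TGACGTCA")
        assert any(h.mismatches == 0 and h.start == 3 for h in hits)

    def test_iupac_classes(self):
        hits = scan_consensus("AATGTCAG", "TGWCAR")
        assert any(h.mismatches == 0 for h in hits)

    def test_one_mismatch_reported_within_budget(self):
        hits = scan_consensus("AAATGACGACAAAA", "TGACGTCA", max_mismatches=2)
        plus = [h for h in hits if h.start == 3 and h.strand == "+"]
        assert plus and plus[0].mismatches == 1

    def test_budget_zero_excludes_mismatched_site(self):
        hits = scan_consensus("AAATGACGACAAAA", "TGACGTCA", max_mismatches=0)
        assert not [h for h in hits if h.start == 3 and h.strand == "+"]

    def test_reverse_strand_detection(self):
        site = "TGACGTTT"
        seq = "CCCC" + _revcomp(site) + "CCCC"
        hits = scan_consensus(seq, site, max_mismatches=0)
        assert any(h.strand == "-" and h.mismatches == 0 for h in hits)

    def test_invalid_iupac_raises(self):
        with pytest.raises(ValueError):
            scan_consensus("ACGT", "AXGT")

    def test_even_length_center_is_left_of_center(self):
        (hit,) = [h for h in scan_consensus("AATGACGTCAAA", "TGACGTCA") if h.strand == "+"]
        assert hit.center_index == hit.start + 3

    def test_matches_exhaustive_oracle_on_random_sequences(self):
        """Independent table-driven window oracle, 100 random sequences."""
        iupac = {
            "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
            "S": "GC", "W": "AT", "K": "GT", "M": "AC", "B": "CGT",
            "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
        }
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
                "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
                "D": "H", "H": "D", "N": "N"}
        rng = np.random.default_rng(10)
        consensus = "TGWCANNTGHCA"
        rc = "".join(comp[c] for c in reversed(consensus))
        for _ in range(100):
            n = int(rng.integers(20, 2000))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            budget = int(rng.integers(0, 4))
            expected = []
            for i in range(n - len(consensus) + 1):
                win = seq[i : i + len(consensus)]
                for strand, cons in (("+", consensus), ("-", rc)):
                    mm = sum(1 for b, c in zip(win, cons) if b not in iupac[c])
                    if mm <= budget:
                        expected.append((i, strand, mm))
            got = [(h.start, h.strand, h.mismatches) for h in scan_consensus(seq, consensus, budget)]
            assert sorted(got) == sorted(expected)


def _revcomp(s):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(s))


class TestScanPromoter:
    def test_planted_site_center_offset(self):
        rng = np.random.default_rng(11)
        for strand in "+-":
            gene = GeneRecord("g", "c", strand, 3000, 4000)
            seq = rng.choice(list("ACGT"), size=8000)
            site = "TGACGTCA"
            # plant on the coding strand with center (left-of-center) at -100
            from capregulon.genome import advance_offset

            start_off = advance_offset(-100, -3)
            positions = sorted(
                tsc_offset_to_genomic(advance_offset(start_off, i), gene) for i in range(8)
            )
            written = site if strand == "+" else _revcomp(site)
            for p, b in zip(positions, written):
                seq[p - 1] = b
            hits = scan_promoter(gene, -500, -1, {"c": "".join(seq)}, site, 0)
            assert -100 in set(hits.center_offset)


class TestDistances:
    def test_worked_four_tss_example(self):
        """Binding site at -409 vs TSSs -297/-213/-171/-135 gives upstream
        distances 112/196/238/274 bp."""
        df = site_tss_distances(-409, [-297, -213, -171, -135])
        assert df.distance_bp.tolist() == [112, 196, 238, 274]

    def test_identity_and_sign(self):
        assert site_tss_distances(-409, [-409]).distance_bp.tolist() == [0]
        assert site_tss_distances(-100, [-200]).distance_bp.tolist() == [-100]

    def test_antisymmetric(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            a, b = (int(x) for x in rng.integers(-500, 500, size=2))
            a = a or 1
            b = b or -1
            assert offset_distance(a, b) == -offset_distance(b, a)

    def test_straddle_correction(self):
        # adjacent bases across the TSC are 1 bp apart despite the missing 0
        assert offset_distance(-1, 1) == 1
        assert offset_distance(-5, 5) == 9

    def test_straddle_matches_genomic_distance(self):
        gene = GeneRecord("g", "c", "+", 1000, 2000)
        rng = np.random.default_rng(13)
        for _ in range(100):
            a, b = (int(x) or 1 for x in rng.integers(-300, 300, size=2))
            ga, gb = tsc_offset_to_genomic(a, gene), tsc_offset_to_genomic(b, gene)
            assert abs(offset_distance(a, b)) == abs(gb - ga)


def test_read_peaks_bed_summits_and_midpoints(tmp_path):
    path = tmp_path / "peaks.bed"
    path.write_text("c\t999\t1000\tp1\t5\t.\nc\t2000\t2010\tp2\t.\t.\n")
    with pytest.warns(UserWarning, match="midpoint"):
        peaks = read_peaks_bed(str(path))
    assert peaks[0].summit == 1000 and peaks[0].score == 5
    assert peaks[1].summit == 2005


def test_promoter_feature_map_sorted():
    df = promoter_feature_map("g", [-297, -135], [-388], [-409])
    assert df.offset.tolist() == [-409, -388, -297, -135]
    assert df.feature.tolist() == ["binding_site", "peak_summit", "tss", "tss"]
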