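"""Read-start counting, RRS normalization, threshold/clustering, replicate
consensus, and gene assignment."""

import numpy as np
import pysam
import pytest

from capregulon.genome import Annotation, GeneRecord
from capregulon.tss import (
    FivePrimeTrack,
    RrsTrack,
    annotate_tss,
    call_tss,
    compute_rrs,
    consensus_tss,
    count_read_starts,
    read_bedgraph_pair,
    write_bedgraph_pair,
)


def _header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
    )


def _aln(header, name, pos, reverse=False, score=0, secondary=False, length=30):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = "A" * length
    a.reference_id = 0
    a.reference_start = pos - 1  # pysam is 0-based
    a.cigarstring = f"{length}M"
    a.flag = (0x10 if reverse else 0) | (0x100 if secondary else 0)
    a.mapping_quality = 30
    a.set_tag("AS", score)
    return a


class TestCountReadStarts:
    def test_single_best_alignment_counts_one(self):
        h = _header()
        track = count_read_starts([_aln(h, "r1", 1000, score=0)])
        assert track.get("chr1", "+", 1000) == 1.0
        assert track.rt == 1.0

    def test_two_equal_best_alignments_half_each(self):
        h = _header()
        alns = [_aln(h, "r1", 1000, score=-2), _aln(h, "r1", 5000, score=-2)]
        track = count_read_starts(alns)
        assert track.get("chr1", "+", 1000) == 0.5
        assert track.get("chr1", "+", 5000) == 0.5
        assert track.rt == 1.0

    def test_suboptimal_alignment_dropped(self):
        h = _header()
        alns = [_aln(h, "r1", 1000, score=0), _aln(h, "r1", 5000, score=-6)]
        track = count_read_starts(alns)
        assert track.get("chr1", "+", 1000) == 1.0
        assert track.get("chr1", "+", 5000) == 0.0

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_k_equal_best_weights_sum_to_one(self, k):
        h = _header()
        alns = [_aln(h, "r1", 1000 * (i + 1), score=0) for i in range(k)]
        track = count_read_starts(alns)
        weights = [track.get("chr1", "+", 1000 * (i + 1)) for i in range(k)]
        assert all(w == pytest.approx(1.0 / k) for w in weights)
        assert sum(weights) == pytest.approx(1.0)
        assert track.rt == 1.0

    def test_reverse_strand_uses_highest_template_coordinate(self):
        h = _header()
        track = count_read_starts([_aln(h, "r1", 2000, reverse=True, length=40)])
        # 5' end of a minus-strand transcript = rightmost aligned base
        assert track.get("chr1", "-", 2039) == 1.0

    def test_missing_score_tag_falls_back_to_primary_flag(self):
        h = _header()
        a1 = _aln(h, "r1", 1000)
        a2 = _aln(h, "r1", 5000, secondary=True)
        for a in (a1, a2):
            a.set_tag("AS", None)
        with pytest.warns(UserWarning, match="AS"):
            track = count_read_starts([a1, a2])
        assert track.get("chr1", "+", 1000) == 1.0
        assert track.rt == 1.0

    def test_weight_conservation_random_reads(self):
        """Per-read alignment weights always sum to 1, so total weight = Rt."""
        h = _header()
        rng = np.random.default_rng(5)
        alns = []
        n_reads = 200
        for i in range(n_reads):
            k = int(rng.integers(1, 5))
            for j in range(int(k)):
                alns.append(_aln(h, f"r{i}", int(rng.integers(1, 90000)), reverse=bool(rng.integers(2)), score=0))
        track = count_read_starts(alns)
        assert track.rt == n_reads
        assert track.total_weight() == pytest.approx(n_reads)

    def test_sam_file_roundtrip(self, tmp_path):
        h = _header()
        path = tmp_path / "reads.sam"
        with pysam.AlignmentFile(path, "w", header=h) as fh:
            fh.write(_aln(h, "r1", 1000, score=-2))
            fh.write(_aln(h, "r1", 5000, score=-2))
            fh.write(_aln(h, "r2", 1000, score=0))
        track = count_read_starts(str(path))
        assert track.get("chr1", "+", 1000) == 1.5
        assert track.rt == 2.0


class TestRrs:
    def test_formula(self):
        track = FivePrimeTrack("r", {("c", "+"): {100: 15.0}}, rt=10_000_000)
        assert compute_rrs(track).scores[("c", "+")][100] == pytest.approx(1.5)

    def test_zero_rt_errors(self):
        with pytest.raises(ValueError):
            compute_rrs(FivePrimeTrack("r", {}, rt=0.0))

    def test_sum_is_one_million(self):
        rng = np.random.default_rng(1)
        track = FivePrimeTrack("r")
        for _ in range(500):
            track.add("c", rng.choice(["+", "-"]), int(rng.integers(1, 10000)), float(rng.integers(1, 50)))
        track.rt = track.total_weight()
        assert compute_rrs(track).total() == pytest.approx(1e6)


def _rrs(scores: dict[int, float], strand="+") -> RrsTrack:
    return RrsTrack("r", {("c", strand): scores})


def _bruteforce_clusters(positions: list[int], gap: int) -> list[set[int]]:
    """Transitive closure over all pairs within gap (independent oracle)."""
    parent = {p: p for p in positions}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for a in positions:
        for b in positions:
            if abs(a - b) <= gap:
                parent[find(a)] = find(b)
    groups: dict[int, set[int]] = {}
    for p in positions:
        groups.setdefault(find(p), set()).add(p)
    return sorted(groups.values(), key=min)


class TestCallTss:
    def test_threshold_is_inclusive(self):
        calls = call_tss(_rrs({100: 1.5, 105: 1.4999}))
        assert [c.max_position for c in calls] == [100]

    def test_all_below_threshold_gives_nothing(self):
        assert call_tss(_rrs({100: 0.2, 101: 1.0})) == []

    def test_spec_clustering_example(self):
        calls = call_tss(_rrs({100: 5.0, 101: 2.0, 105: 3.0}), cluster_gap=3)
        assert len(calls) == 2
        assert set(calls[0].members) == {100, 101} and calls[0].max_position == 100
        assert set(calls[1].members) == {105}

    def test_singleton(self):
        (call,) = call_tss(_rrs({77: 7.2}))
        assert call.max_position == 77 and call.cluster_start == call.cluster_end == 77

    def test_flanking_clusters_merge_transitively(self):
        calls = call_tss(_rrs({100: 2.0, 103: 2.0, 106: 5.0}), cluster_gap=3)
        assert len(calls) == 1 and calls[0].max_position == 106

    @pytest.mark.parametrize("strand,expected", [("+", 100), ("-", 103)])
    def test_max_tie_breaks_to_five_prime_most(self, strand, expected):
        (call,) = call_tss(_rrs({100: 4.0, 103: 4.0}, strand=strand), cluster_gap=3)
        assert call.max_position == expected

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(1, 50))
            positions = sorted(set(rng.integers(1, 300, size=n).tolist()))
            gap = int(rng.integers(1, 6))
            scores = {int(p): float(rng.uniform(1.5, 50)) for p in positions}
            calls = call_tss(_rrs(scores), threshold=1.5, cluster_gap=gap)
            expected = _bruteforce_clusters(list(scores), gap)
            assert [set(c.members) for c in calls] == expected
            for c in calls:
                assert c.members[c.max_position] == max(c.members.values())


def _call(pos, rrs=5.0, strand="+", rep="r1"):
    from capregulon.tss import TssCall

    return TssCall("c", strand, pos, pos, pos, {rep: rrs}, {pos: rrs})


class TestConsensus:
    def test_nearby_maxima_match(self):
        out = consensus_tss([[_call(500, 5.0, rep="r1")], [_call(502, 3.0, rep="r2")]], tolerance=3)
        (c,) = out
        assert c.reproducible and c.max_position == 500  # higher-RRS replicate wins
        assert c.max_rrs == {"r1": 5.0, "r2": 3.0}

    def test_unmatched_call_not_reproducible(self):
        out = consensus_tss([[_call(500)], []], tolerance=3)
        assert len(out) == 1 and out[0].reproducible is False

    def test_identical_replicates_idempotent(self):
        out = consensus_tss([[_call(500, rep="r1")], [_call(500, rep="r2")]])
        (c,) = out
        assert c.reproducible and c.max_position == 500

    def test_beyond_tolerance_not_matched(self):
        out = consensus_tss([[_call(500, rep="r1")], [_call(504, rep="r2")]], tolerance=3)
        assert all(not c.reproducible for c in out) and len(out) == 2

    def test_single_replicate_passthrough_warns(self):
        with pytest.warns(UserWarning):
            out = consensus_tss([[_call(500)]])
        assert len(out) == 1 and out[0].reproducible is False

    def test_m_of_n(self):
        reps = [[_call(500, rep="r1")], [_call(501, rep="r2")], []]
        assert all(not c.reproducible for c in consensus_tss(reps, min_replicates=None))
        out = consensus_tss(reps, min_replicates=2)
        assert any(c.reproducible for c in out)


class TestAnnotate:
    def setup_method(self):
        self.ann = Annotation(
            [
                GeneRecord("gplus", "c", "+", 2000, 3000),
                GeneRecord("gminus", "c", "-", 100, 900),
            ]
        )

    def test_upstream_tss_assigned_with_offset(self):
        table = annotate_tss([_call(1703)], self.ann)
        row = table[table.gene_id == "gplus"].iloc[0]
        assert row.offset == -297

    def test_outside_window_unassigned(self):
        table = annotate_tss([_call(1400)], self.ann, assign_window=(-500, 100))
        assert (table.gene_id == "").all()

    def test_divergent_genes_same_strand_only(self):
        ann = Annotation(
            [
                GeneRecord("right", "c", "+", 1100, 2000),
                GeneRecord("left", "c", "-", 100, 900),
            ]
        )
        table = annotate_tss([_call(1000, strand="+")], ann)
        assert list(table.gene_id) == ["right"]


def test_bedgraph_roundtrip(tmp_path):
    rng = np.random.default_rng(9)
    track = FivePrimeTrack("rep1")
    for _ in range(300):
        track.add("c", rng.choice(["+", "-"]), int(rng.integers(1, 5000)), float(rng.integers(1, 9)) / 2)
    track.rt = track.total_weight() + 100  # Rt can exceed represented weight
    plus, minus = tmp_path / "p.bedgraph", tmp_path / "m.bedgraph"
    write_bedgraph_pair(track, str(plus), str(minus))
    back = read_bedgraph_pair(str(plus), str(minus), replicate_id="rep1")
    assert back.rt == track.rt
    assert back.counts == track.counts
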