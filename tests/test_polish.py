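"""Segment partitioning, pileup edit calling, aggregation, application."""

import numpy as np
import pytest

from lathework import (
    ContigRecord,
    ConsensusEdit,
    GenomeSpec,
    ReadAlignment,
    ReadSet,
    aggregate_edits,
    apply_edits,
    build_pileup,
    call_segment_edits,
    downsample_to_depth,
    flag_homopolymer_edits,
    make_genome,
    map_reads_anchored,
    mutate_assembly,
    partition_segments,
    polish_assembly,
    read_edits_vcf,
    simulate_short_reads,
    write_edits_vcf,
)
from lathework.core import GenomicInterval
from lathework.polish import Segment


def _seg(contig="c", start=0, end=100, index=0):
    return Segment(interval=GenomicInterval(contig, start, end), index=index)


def _aln(contig, start, end, read_id, strand="+", cigar=None):
    return ReadAlignment(
        read_id=read_id, contig_id=contig, ref_start=start, ref_end=end,
        strand=strand, cigar=cigar or f"{end - start}M",
    )


class TestPartitionSegments:
    def _contig(self, n):
        return ContigRecord(id="c", seq="A" * n)

    def test_exact_and_remainder(self):
        segs = partition_segments([self._contig(250_000)], 100_000)
        assert [(s.interval.start, s.interval.end) for s in segs] == [
            (0, 100_000), (100_000, 200_000), (200_000, 250_000)
        ]

    def test_short_contig_single_segment(self):
        segs = partition_segments([self._contig(40_000)], 100_000)
        assert [(s.interval.start, s.interval.end) for s in segs] == [(0, 40_000)]

    def test_small_remainder_merged(self):
        segs = partition_segments([self._contig(149_000)], 100_000)
        assert [(s.interval.start, s.interval.end) for s in segs] == [(0, 149_000)]

    def test_indices_global_and_cover(self):
        contigs = [ContigRecord(id="a", seq="A" * 150_000),
                   ContigRecord(id="b", seq="C" * 120_000)]
        segs = partition_segments(contigs, 50_000)
        assert [s.index for s in segs] == list(range(len(segs)))
        for cid, L in (("a", 150_000), ("b", 120_000)):
            own = [s for s in segs if s.interval.contig_id == cid]
            assert own[0].interval.start == 0 and own[-1].interval.end == L


class TestDownsample:
    def _alns(self, n, L=1000, read_len=100, seed=0):
        rng = np.random.default_rng(seed)
        return [
            _aln("c", s, s + read_len, f"r{i}")
            for i, s in enumerate(rng.integers(0, L - read_len, size=n))
        ]

    def test_below_target_keeps_all(self):
        alns = self._alns(30)  # mean depth 3x over 1 kb
        seg = _seg(end=1000)
        assert downsample_to_depth(alns, seg, target_depth=50) == alns

    def test_high_depth_downsampled_near_target(self):
        alns = self._alns(1000)  # ~100x
        seg = _seg(end=1000)
        for seed in (0, 1, 2):
            kept = downsample_to_depth(alns, seg, target_depth=50, seed=seed)
            depth = sum(a.ref_span for a in kept) / 1000
            assert 40 <= depth <= 60

    def test_deterministic_and_order_independent(self):
        alns = self._alns(500)
        seg = _seg(end=1000)
        a = downsample_to_depth(alns, seg, target_depth=20, seed=7)
        b = downsample_to_depth(alns[::-1], seg, target_depth=20, seed=7)
        assert {x.read_id for x in a} == {x.read_id for x in b}

    def test_mean_retained_depth_unbiased(self):
        alns = self._alns(1200)  # ~120x: >= 2x target
        seg = _seg(end=1000)
        depths = []
        for seed in range(100):
            kept = downsample_to_depth(alns, seg, target_depth=50, seed=seed)
            depths.append(sum(a.ref_span for a in kept) / 1000)
        assert abs(np.mean(depths) - 50) <= 5


class TestBuildPileup:
    def test_identical_perfect_reads(self):
        ref = ContigRecord(id="c", seq="ACGTACGTAC")
        reads = ReadSet(reads=[(f"r{i}", ref.seq, None) for i in range(10)])
        alns = [_aln("c", 0, 10, f"r{i}") for i in range(10)]
        pile = build_pileup(_seg(end=10), alns, reads)
        col = pile.column(0)
        assert col.base_counts["A"] == 10
        assert pile.depth().tolist() == [10] * 10

    def test_deletion_counted_at_deleted_position(self):
        ref_len = 11
        reads = ReadSet(reads=[("r", "AAAAACCCCC", None)])
        alns = [_aln("c", 0, ref_len, "r", cigar="5M1D5M")]
        pile = build_pileup(_seg(end=ref_len), alns, reads)
        assert pile.column(5).base_counts["del"] == 1
        assert pile.column(4).base_counts["del"] == 0

    def test_insertion_recorded_after_anchor(self):
        reads = ReadSet(reads=[("r", "AAAAAGGCCCCC", None)])
        alns = [_aln("c", 0, 10, "r", cigar="5M2I5M")]
        pile = build_pileup(_seg(end=10), alns, reads)
        assert pile.column(4).insertion_counts == {"GG": 1}

    def test_inconsistent_cigar_rejected(self):
        reads = ReadSet(reads=[("r", "ACGT", None)])
        alns = [_aln("c", 0, 10, "r", cigar="10M")]
        with pytest.raises(ValueError, match="r"):
            build_pileup(_seg(end=10), alns, reads)

    def test_low_quality_bases_excluded(self):
        reads = ReadSet(reads=[("r", "ACGT", "I!I!")])  # phred 40,0,40,0
        alns = [_aln("c", 0, 4, "r")]
        pile = build_pileup(_seg(end=4), alns, reads, min_base_q=20)
        assert pile.depth().tolist() == [1, 0, 1, 0]


class TestCallEdits:
    def _pileup_from_counts(self, ref, column_reads):
        reads = ReadSet(reads=[
            (f"r{i}", seq, None) for i, seq in enumerate(column_reads)
        ])
        alns = [_aln("c", 0, len(ref.seq), f"r{i}")
                for i in range(len(column_reads))]
        return build_pileup(_seg(end=len(ref.seq)), alns, reads)

    def test_clear_substitution_called(self):
        ref = ContigRecord(id="c", seq="AAAAA")
        observations = ["AAGAA"] * 48 + ["AAAAA"] * 2
        pile = self._pileup_from_counts(ref, observations)
        edits = call_segment_edits(_seg(end=5), pile, ref)
        assert len(edits) == 1
        ed = edits[0]
        assert (ed.pos, ed.ref_allele, ed.alt_allele) == (2, "A", "G")
        assert ed.alt_support == 48 and ed.depth == 50

    def test_tie_breaks_toward_reference(self):
        ref = ContigRecord(id="c", seq="AAAAA")
        pile = self._pileup_from_counts(
            ref, ["AAGAA"] * 25 + ["AAAAA"] * 25
        )
        assert call_segment_edits(_seg(end=5), pile, ref,
                                  min_alt_frac=0.5) == []

    def test_depth_threshold(self):
        ref = ContigRecord(id="c", seq="AAAAA")
        pile = self._pileup_from_counts(ref, ["AAGAA"] * 3)
        assert call_segment_edits(_seg(end=5), pile, ref, min_depth=5) == []


class TestAggregate:
    def _ed(self, pos, ref, alt, support, contig="c"):
        return ConsensusEdit(contig, pos, ref, alt, depth=max(support, 50),
                             alt_support=support)

    def test_duplicate_edit_deduplicated(self):
        e1 = self._ed(10, "A", "G", 30)
        e2 = self._ed(10, "A", "G", 35)
        merged = aggregate_edits([[e1], [e2]])
        assert len(merged) == 1 and merged[0].alt_support == 35

    def test_overlapping_conflict_resolved_by_support(self):
        deletion = ConsensusEdit("c", 10, "ACGTA", "", depth=50, alt_support=30)
        sub = self._ed(12, "G", "T", 10)
        merged = aggregate_edits([[deletion], [sub]])
        assert merged == [deletion]

    def test_disjoint_edits_sorted(self):
        e1 = self._ed(50, "A", "G", 10)
        e2 = self._ed(10, "C", "T", 10)
        merged = aggregate_edits([[e1], [e2]])
        assert [e.pos for e in merged] == [10, 50]


class TestApplyEdits:
    def test_no_edits_identity(self):
        c = ContigRecord(id="c", seq="ACGTACGT")
        assert apply_edits([c], [])[0].seq == c.seq

    def test_single_substitution(self):
        c = ContigRecord(id="c", seq="AAAAA")
        out = apply_edits([c], [ConsensusEdit("c", 2, "A", "G")])
        assert out[0].seq == "AAGAA"

    def test_indels_shift_length_by_signed_sum(self):
        c = ContigRecord(id="c", seq="AACCGGTT")
        edits = [
            ConsensusEdit("c", 1, "A", ""),     # -1
            ConsensusEdit("c", 4, "", "TTT"),   # +3
        ]
        out = apply_edits([c], edits)
        assert len(out[0].seq) == len(c.seq) + 2
        assert out[0].seq == "ACCTTTGGTT"

    def test_mismatching_ref_allele_rejected(self):
        c = ContigRecord(id="c", seq="AAAAA")
        with pytest.raises(ValueError):
            apply_edits([c], [ConsensusEdit("c", 2, "G", "T")])

    def test_truth_edits_invert_mutations(self):
        genome, _ = make_genome(GenomeSpec(length=30_000, seed=1))
        draft, truth = mutate_assembly(genome, 20, 8, 8, seed=2)
        restored = apply_edits([draft], truth)
        assert restored[0].seq == genome.seq


class TestLeftAlignEdit:
    def test_indels_in_runs_share_a_canonical_key(self):
        from lathework.polish import left_align_edit

        seq = "ACGTTTTTACG"  # T-run occupies [3, 8)
        # deleting any T of the run is the same correction
        keys = {
            left_align_edit(ConsensusEdit("c", p, "T", ""), seq)
            for p in range(3, 8)
        }
        assert keys == {("c", 3, "T", "")}
        # inserting a T anywhere in/after the run is the same correction
        keys = {
            left_align_edit(ConsensusEdit("c", p, "", "T"), seq)
            for p in range(3, 9)
        }
        assert keys == {("c", 3, "", "T")}
        # substitutions are never moved
        assert left_align_edit(ConsensusEdit("c", 6, "T", "G"), seq) == \
            ("c", 6, "T", "G")


class TestHomopolymerFlagging:
    def _ref(self, seq):
        return [ContigRecord(id="c", seq=seq)]

    def test_deletion_inside_run_flagged(self):
        ref = self._ref("GGCAAAAACGG")
        (ed,) = flag_homopolymer_edits(
            [ConsensusEdit("c", 5, "A", "")], ref, min_run=4
        )
        assert ed.homopolymer

    def test_substitution_without_run_not_flagged(self):
        ref = self._ref("ACGTACGT")
        (ed,) = flag_homopolymer_edits(
            [ConsensusEdit("c", 3, "T", "G")], ref, min_run=4
        )
        assert not ed.homopolymer

    def test_insertion_adjacent_to_run_flagged(self):
        ref = self._ref("CGTTTTCGCA")
        (ed,) = flag_homopolymer_edits(
            [ConsensusEdit("c", 6, "", "T")], ref, min_run=4
        )
        assert ed.homopolymer


class TestVcfRoundTrip:
    def test_edits_survive_round_trip(self, tmp_path):
        genome, _ = make_genome(GenomeSpec(length=5_000, seed=3))
        edits = [
            ConsensusEdit(genome.id, 100, genome.seq[100], "G"
                          if genome.seq[100] != "G" else "T",
                          depth=50, alt_support=48),
            ConsensusEdit(genome.id, 200, genome.seq[200], "",
                          depth=44, alt_support=40, homopolymer=True),
            ConsensusEdit(genome.id, 300, "", "TA", depth=30, alt_support=28),
        ]
        p = tmp_path / "edits.vcf"
        write_edits_vcf(edits, [genome], p)
        back = read_edits_vcf(p, [genome])
        assert [(e.pos, e.ref_allele, e.alt_allele, e.depth, e.alt_support,
                 e.homopolymer) for e in back] == \
               [(e.pos, e.ref_allele, e.alt_allele, e.depth, e.alt_support,
                 e.homopolymer) for e in edits]


class TestEndToEnd:
    def _fixture(self, seed, length=60_000, n_subs=20, n_ins=6, n_del=6):
        genome, _ = make_genome(GenomeSpec(length=length, seed=seed))
        draft, truth = mutate_assembly(genome, n_subs, n_ins, n_del,
                                       seed=seed + 1)
        sim = simulate_short_reads(genome, depth=50, seed=seed + 2)
        alns = map_reads_anchored(sim.reads, [draft])
        return genome, draft, sim.reads, alns

    def test_planted_errors_corrected(self):
        genome, draft, reads, alns = self._fixture(seed=10)
        res = polish_assembly([draft], alns, reads, segment_bp=20_000, seed=1)
        assert res.polished[0].seq == genome.seq

    def test_clean_input_yields_zero_edits(self):
        genome, _ = make_genome(GenomeSpec(length=40_000, seed=20))
        sim = simulate_short_reads(genome, depth=40, seed=21)
        alns = map_reads_anchored(sim.reads, [genome])
        res = polish_assembly([genome], alns, sim.reads, segment_bp=20_000,
                              seed=1)
        assert res.edits == []
        assert res.polished[0].seq == genome.seq

    def test_invariant_to_segment_order_and_size(self):
        genome, draft, reads, alns = self._fixture(seed=30)
        base = polish_assembly([draft], alns, reads, segment_bp=20_000, seed=1)
        n_seg = len(base.segments)
        permuted = polish_assembly(
            [draft], alns, reads, segment_bp=20_000, seed=1,
            segment_order=list(reversed(range(n_seg))),
        )
        other_size = polish_assembly(
            [draft], alns, reads, segment_bp=13_000, seed=1
        )
        assert permuted.polished[0].seq == base.polished[0].seq
        assert other_size.polished[0].seq == base.polished[0].seq
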