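"""Spanned-window misassembly screen: windowing, counting, breaking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lathework import (
    ContigRecord,
    GenomeSpec,
    ReadAlignment,
    ReadSet,
    ReadSimParams,
    break_contigs,
    call_breaks,
    choose_window_size,
    count_spanning,
    flag_unsupported,
    make_genome,
    map_reads_anchored,
    mean_read_length,
    plant_chimera,
    screen_assembly,
    simulate_long_reads,
    tile_windows,
)
from lathework.misassembly import BreakSite, SpanWindow
from lathework.core import GenomicInterval


def _aln(contig, start, end, read_id="r", mapq=60, primary=True, **kw):
    return ReadAlignment(
        read_id=read_id, contig_id=contig, ref_start=start, ref_end=end,
        strand="+", mapq=mapq, is_primary=primary, **kw,
    )


class TestMeanReadLength:
    def test_reads(self):
        rs = ReadSet(reads=[("a", "A" * 1000, None), ("b", "C" * 3000, None)])
        assert mean_read_length(rs) == 2000.0

    def test_single(self):
        assert mean_read_length(ReadSet(reads=[("a", "A" * 500, None)])) == 500.0

    def test_alignment_includes_clips(self):
        a = _aln("c", 0, 80, cigar="10S80M10S", left_clip=10, right_clip=10)
        assert mean_read_length([a]) == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_read_length([])


class TestChooseWindowSize:
    @pytest.mark.parametrize(
        "mean,expected", [(8000, 6000), (400, 500), (1e6, 20000)]
    )
    def test_formula_and_clamps(self, mean, expected):
        assert choose_window_size(mean, 0.75, 500, 20000) == expected

    def test_bad_factor(self):
        with pytest.raises(ValueError):
            choose_window_size(5000, factor=1.5)


class TestTileWindows:
    @pytest.mark.parametrize(
        "length,window,expected",
        [
            (300, 100, [(0, 100), (100, 200), (200, 300)]),
            (250, 100, [(0, 100), (100, 200), (200, 250)]),
            (230, 100, [(0, 100), (100, 230)]),
            (80, 100, [(0, 80)]),
        ],
    )
    def test_tiling_rules(self, length, window, expected):
        contig = ContigRecord(id="c", seq="A" * length)
        got = [(w.interval.start, w.interval.end) for w in tile_windows(contig, window)]
        assert got == expected

    @given(length=st.integers(1, 5000), window=st.integers(1, 700))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_windows_partition_contig(self, length, window):
        contig = ContigRecord(id="c", seq="A" * length)
        ws = tile_windows(contig, window)
        assert ws[0].interval.start == 0 and ws[-1].interval.end == length
        for a, b in zip(ws, ws[1:]):
            assert a.interval.end == b.interval.start


def brute_force_counts(windows, alignments, min_mapq=10, primary_only=True):
    out = []
    for w in windows:
        n = sum(
            1
            for a in alignments
            if a.contig_id == w.interval.contig_id
            and a.mapq >= min_mapq
            and (a.is_primary or not primary_only)
            and a.ref_start <= w.interval.start
            and a.ref_end >= w.interval.end
        )
        out.append(n)
    return out


class TestCountSpanning:
    def test_worked_example(self):
        contig = ContigRecord(id="c", seq="A" * 300)
        ws = tile_windows(contig, 100)
        alns = [
            _aln("c", 0, 300, "r1"),
            _aln("c", 50, 250, "r2"),
            _aln("c", 120, 180, "r3"),
        ]
        counted = count_spanning(ws, alns)
        assert [w.spanning_count for w in counted] == [1, 2, 1]

    def test_no_alignments(self):
        ws = tile_windows(ContigRecord(id="c", seq="A" * 300), 100)
        assert [w.spanning_count for w in count_spanning(ws, [])] == [0, 0, 0]

    def test_exact_boundary_spans(self):
        ws = tile_windows(ContigRecord(id="c", seq="A" * 300), 100)
        counted = count_spanning(ws, [_aln("c", 100, 200)])
        assert [w.spanning_count for w in counted] == [0, 1, 0]

    def test_mapq_and_primary_filters(self):
        ws = tile_windows(ContigRecord(id="c", seq="A" * 100), 100)
        alns = [
            _aln("c", 0, 100, "lowq", mapq=5),
            _aln("c", 0, 100, "supp", primary=False),
            _aln("c", 0, 100, "good"),
        ]
        assert count_spanning(ws, alns)[0].spanning_count == 1

    def test_unknown_contig_rejected(self):
        ws = tile_windows(ContigRecord(id="c", seq="A" * 100), 100)
        with pytest.raises(ValueError, match="zzz"):
            count_spanning(ws, [_aln("zzz", 0, 50)])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(60):
            L = int(rng.integers(200, 2000))
            n_windows = int(rng.integers(1, 20))
            n_alns = int(rng.integers(0, 40))
            windows = []
            for _ in range(n_windows):
                s = int(rng.integers(0, L - 1))
                e = int(rng.integers(s + 1, L + 1))
                windows.append(SpanWindow(interval=GenomicInterval("c", s, e)))
            alns = []
            for i in range(n_alns):
                s = int(rng.integers(0, L - 1))
                e = int(rng.integers(s + 1, L + 1))
                alns.append(
                    _aln("c", s, e, f"r{i}", mapq=int(rng.integers(0, 61)),
                         primary=bool(rng.random() < 0.8))
                )
            got = [w.spanning_count for w in count_spanning(windows, alns)]
            assert got == brute_force_counts(windows, alns)


class TestFlagging:
    def _windows(self, counts, window=100):
        return [
            SpanWindow(
                interval=GenomicInterval("c", i * window, (i + 1) * window),
                spanning_count=n,
            )
            for i, n in enumerate(counts)
        ]

    def test_threshold_one_or_zero(self):
        ws = flag_unsupported(self._windows([1, 2, 1]), max_support=1,
                              edge_exempt_bp=0, contig_len=300)
        assert [w.flagged for w in ws] == [True, False, True]

    def test_terminal_window_exempt(self):
        ws = flag_unsupported(self._windows([0, 5, 5]), max_support=1,
                              edge_exempt_bp=100, contig_len=300)
        assert ws[0].exempt and not ws[0].flagged

    def test_well_supported_not_flagged(self):
        ws = flag_unsupported(self._windows([2, 3, 4]), max_support=1,
                              edge_exempt_bp=0, contig_len=300)
        assert not any(w.flagged for w in ws)


class TestCallBreaks:
    def _flagged(self, spans):
        return [
            SpanWindow(interval=GenomicInterval("c", s, e),
                       spanning_count=n, flagged=True)
            for s, e, n in spans
        ]

    def test_single_window_midpoint(self):
        (b,) = call_breaks(self._flagged([(100, 200, 0)]))
        assert b.position == 150

    def test_adjacent_windows_merged(self):
        (b,) = call_breaks(self._flagged([(100, 200, 1), (200, 300, 0)]))
        assert b.position == 200
        assert b.spanning_count == 0

    def test_empty(self):
        assert call_breaks([]) == []


class TestBreakContigs:
    def test_single_split(self):
        c = ContigRecord(id="c", seq="A" * 150 + "G" * 150)
        frags = break_contigs(
            [c], [BreakSite("c", 150, GenomicInterval("c", 100, 200), 0)],
            min_fragment_bp=0,
        )
        assert [f.seq for f in frags] == ["A" * 150, "G" * 150]
        assert [f.id for f in frags] == ["c_b1", "c_b2"]

    def test_multi_split_conserves_bases(self):
        c = ContigRecord(id="c", seq="ACGT" * 75)
        sites = [
            BreakSite("c", p, GenomicInterval("c", p - 50, p + 50), 0)
            for p in (100, 200)
        ]
        frags = break_contigs([c], sites, min_fragment_bp=0)
        assert [len(f.seq) for f in frags] == [100, 100, 100]
        assert "".join(f.seq for f in frags) == c.seq

    def test_short_fragments_dropped(self, caplog):
        c = ContigRecord(id="c", seq="A" * 300)
        frags = break_contigs(
            [c], [BreakSite("c", 150, GenomicInterval("c", 100, 200), 0)],
            min_fragment_bp=200,
        )
        assert frags == []

    def test_circular_flag_cleared(self):
        c = ContigRecord(id="c", seq="A" * 4000, circular=True)
        frags = break_contigs(
            [c], [BreakSite("c", 2000, GenomicInterval("c", 1500, 2500), 0)]
        )
        assert all(not f.circular for f in frags)

    def test_unknown_contig_rejected(self):
        with pytest.raises(ValueError):
            break_contigs(
                [ContigRecord(id="c", seq="A" * 300)],
                [BreakSite("x", 10, GenomicInterval("x", 0, 20), 0)],
            )


class TestEndToEnd:
    def test_planted_chimera_recovered_and_clean_contig_unbroken(self):
        a, _ = make_genome(GenomeSpec(length=60_000, seed=20))
        b, _ = make_genome(GenomeSpec(length=60_000, seed=21))
        chim, _ = plant_chimera(a, b, 30_000, 30_000)
        alns = []
        for g, sd in ((a, 22), (b, 23)):
            sim = simulate_long_reads(g, ReadSimParams(depth=30, seed=sd))
            alns += map_reads_anchored(sim.reads, [chim])
        broken, windows, breaks = screen_assembly(
            [chim], alns, window_factor=0.25
        )
        wsize = len(windows[0].interval)
        assert len(breaks) == 1
        assert abs(breaks[0].position - 30_000) <= wsize
        assert sum(len(f.seq) for f in broken) == len(chim.seq)

    def test_rescreen_of_fragments_finds_no_new_breaks(self):
        a, _ = make_genome(GenomeSpec(length=60_000, seed=24))
        b, _ = make_genome(GenomeSpec(length=60_000, seed=25))
        chim, _ = plant_chimera(a, b, 30_000, 30_000)
        reads = []
        for g, sd in ((a, 26), (b, 27)):
            reads.append(simulate_long_reads(g, ReadSimParams(depth=30, seed=sd)).reads)
        alns = [x for rs in reads for x in map_reads_anchored(rs, [chim])]
        broken, _, breaks = screen_assembly([chim], alns, window_factor=0.25)
        assert breaks
        # second round against the fragments: edge exemption active
        alns2 = [x for rs in reads for x in map_reads_anchored(rs, broken)]
        _, _, breaks2 = screen_assembly(broken, alns2, window_factor=0.25)
        assert breaks2 == []
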