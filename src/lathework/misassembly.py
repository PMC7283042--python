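"""Spanned-window misassembly detection and contig breaking.

A misassembled junction cannot be crossed by reads from the true genomes:
alignments get soft-clipped at the breakpoint, so no (or almost no) read
spans a window containing it. The screen tiles each contig into windows
smaller than the mean read length, counts reads whose aligned reference
interval fully contains each window, flags windows supported by at most
``max_support`` spanning reads, and breaks contigs at the midpoint of each
flagged region. Windows touching the contig termini are exempt by default:
reads cannot overhang a linear contig end, so sparse spanning there is not
evidence of misassembly.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, insort
from dataclasses import dataclass, replace
from typing import Sequence, Union

from .core import ContigRecord, GenomicInterval, ReadAlignment, ReadSet

__all__ = [
    "SpanWindow",
    "BreakSite",
    "mean_read_length",
    "choose_window_size",
    "tile_windows",
    "count_spanning",
    "flag_unsupported",
    "call_breaks",
    "break_contigs",
    "screen_assembly",
]

logger = logging.getLogger(__name__)


@dataclass
class SpanWindow:
    """A tiling window with its spanning-read count."""

    interval: GenomicInterval
    spanning_count: int = 0
    exempt: bool = False
    flagged: bool = False


@dataclass
class BreakSite:
    """A position at which a contig is to be broken."""

    contig_id: str
    position: int
    source_window: GenomicInterval
    spanning_count: int


def mean_read_length(
    reads_or_alignments: Union[ReadSet, Sequence[ReadAlignment]],
) -> float:
    """Arithmetic mean read length.

    For alignments the full read length is the aligned query span plus both
    clips, so clipped reads contribute their true length.
    """
    if isinstance(reads_or_alignments, ReadSet):
        lengths = reads_or_alignments.lengths()
    else:
        lengths = [a.read_length for a in reads_or_alignments]
    if not lengths:
        raise ValueError("cannot take mean read length of empty input")
    return sum(lengths) / len(lengths)


def choose_window_size(
    mean_read_len: float,
    factor: float = 0.75,
    floor_bp: int = 500,
    cap_bp: int = 20000,
) -> int:
    """Window size = clamp(round(factor * mean read length), floor, cap).

    The factor < 1 leaves margin so that a typical read can span a window it
    mostly overlaps.
    """
    if not (0 < factor < 1):
        raise ValueError("factor must be in (0, 1)")
    return int(min(cap_bp, max(floor_bp, round(factor * mean_read_len))))


def tile_windows(
    contig: ContigRecord, window: int, offset: int = 0
) -> list[SpanWindow]:
    """Tile [0, len) into non-overlapping windows; a trailing partial window
    shorter than window/2 is merged into the previous one.

    A nonzero ``offset`` starts the tiling grid at that position (with a
    leading partial window); the screen runs a second, half-window-shifted
    phase so that no genome position sits exactly on the edges of every
    window it is evaluated in.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 0 <= offset < window:
        raise ValueError("offset must be in [0, window)")
    L = len(contig.seq)
    edges = sorted({0, *range(offset, L, window), L})
    if len(edges) > 2 and edges[-1] - edges[-2] < window / 2:
        del edges[-2]
    return [
        SpanWindow(interval=GenomicInterval(contig.id, s, e))
        for s, e in zip(edges, edges[1:])
    ]


def count_spanning(
    windows: list[SpanWindow],
    alignments: Sequence[ReadAlignment],
    min_mapq: int = 10,
    primary_only: bool = True,
    contig_ids: Sequence[str] | None = None,
) -> list[SpanWindow]:
    """Count, per window, alignments whose reference interval fully contains
    it (ref_start <= w.start and ref_end >= w.end). Clips are ignored: the
    spanning test uses the aligned span only, because misassemblies manifest
    as clipped alignments that stop at the breakpoint."""
    if contig_ids is None:
        contig_ids = {w.interval.contig_id for w in windows}
    known = set(contig_ids)
    qualifying: dict[str, list[ReadAlignment]] = {}
    for a in alignments:
        if a.contig_id not in known:
            raise ValueError(
                f"alignment references unknown contig {a.contig_id!r}"
            )
        if a.mapq < min_mapq or (primary_only and not a.is_primary):
            continue
        qualifying.setdefault(a.contig_id, []).append(a)
    idx_by_contig: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        idx_by_contig.setdefault(w.interval.contig_id, []).append(i)
    out: list[SpanWindow | None] = [None] * len(windows)
    for cid, idxs in idx_by_contig.items():
        alns = sorted(qualifying.get(cid, []), key=lambda a: a.ref_start)
        # sweep windows by start, admitting alignments with
        # ref_start <= window.start, then count admitted ref_ends >= w.end
        idxs.sort(key=lambda i: windows[i].interval.start)
        admitted_ends: list[int] = []
        ai = 0
        for i in idxs:
            w = windows[i]
            while ai < len(alns) and alns[ai].ref_start <= w.interval.start:
                insort(admitted_ends, alns[ai].ref_end)
                ai += 1
            n = len(admitted_ends) - bisect_left(admitted_ends, w.interval.end)
            out[i] = replace(w, spanning_count=n)
    return out  # type: ignore[return-value]


def flag_unsupported(
    windows: list[SpanWindow],
    max_support: int = 1,
    edge_exempt_bp: int = 0,
    contig_len: int | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> list[SpanWindow]:
    """Flag windows with spanning_count <= max_support; windows overlapping
    the terminal ``edge_exempt_bp`` of the contig are marked exempt instead."""
    if max_support < 0:
        raise ValueError("max_support must be >= 0")
    out = []
    for w in windows:
        if contig_lengths is not None:
            L = contig_lengths[w.interval.contig_id]
        elif contig_len is not None:
            L = contig_len
        else:
            raise ValueError("contig length required")
        exempt = edge_exempt_bp > 0 and (
            w.interval.start < edge_exempt_bp
            or w.interval.end > L - edge_exempt_bp
        )
        flagged = (not exempt) and w.spanning_count <= max_support
        out.append(replace(w, exempt=exempt, flagged=flagged))
    return out


def call_breaks(flagged: list[SpanWindow]) -> list[BreakSite]:
    """Merge adjacent or overlapping flagged windows and place one break at
    each merged region's midpoint; the region minimum spanning count is
    recorded."""
    regions: list[tuple[str, int, int, int]] = []
    for w in sorted(
        (w for w in flagged if w.flagged),
        key=lambda w: (w.interval.contig_id, w.interval.start),
    ):
        cid, s, e = w.interval.contig_id, w.interval.start, w.interval.end
        if regions and regions[-1][0] == cid and regions[-1][2] >= s:
            pc, ps, pe, pn = regions[-1]
            regions[-1] = (pc, ps, max(pe, e), min(pn, w.spanning_count))
        else:
            regions.append((cid, s, e, w.spanning_count))
    return [
        BreakSite(
            contig_id=cid,
            position=(s + e) // 2,
            source_window=GenomicInterval(cid, s, e),
            spanning_count=n,
        )
        for cid, s, e, n in regions
    ]


def break_contigs(
    assembly: Sequence[ContigRecord],
    breaks: Sequence[BreakSite],
    min_fragment_bp: int = 1000,
) -> list[ContigRecord]:
    """Split contigs at break positions; fragments get deterministic ``_bN``
    suffixes in coordinate order, slivers below min_fragment_bp are dropped
    (logged), and the circular flag is cleared on fragments of broken
    contigs."""
    by_contig: dict[str, list[int]] = {}
    known = {c.id for c in assembly}
    for b in breaks:
        if b.contig_id not in known:
            raise ValueError(f"break on unknown contig {b.contig_id!r}")
        by_contig.setdefault(b.contig_id, []).append(b.position)
    out: list[ContigRecord] = []
    for contig in assembly:
        positions = sorted(set(by_contig.get(contig.id, [])))
        if not positions:
            out.append(contig)
            continue
        if any(not (0 < p < len(contig.seq)) for p in positions):
            raise ValueError(
                f"break position outside contig {contig.id!r} interior"
            )
        edges = [0] + positions + [len(contig.seq)]
        for i, (s, e) in enumerate(zip(edges, edges[1:]), start=1):
            frag_seq = contig.seq[s:e]
            if len(frag_seq) < min_fragment_bp:
                logger.warning(
                    "dropping fragment %s_b%d (%d bp < %d bp minimum)",
                    contig.id, i, len(frag_seq), min_fragment_bp,
                )
                continue
            out.append(
                ContigRecord(
                    id=f"{contig.id}_b{i}",
                    seq=frag_seq,
                    circular=False,
                    provenance=f"broken from {contig.id} at [{s}:{e}]",
                )
            )
    return out


def screen_assembly(
    assembly: Sequence[ContigRecord],
    alignments: Sequence[ReadAlignment],
    window_bp: int | None = None,
    window_factor: float = 0.75,
    max_support: int = 1,
    min_mapq: int = 10,
    edge_exempt_bp: int | None = None,
    min_fragment_bp: int = 1000,
) -> tuple[list[ContigRecord], list[SpanWindow], list[BreakSite]]:
    """Full screen: choose window size, tile, count, flag, break.

    Returns (broken assembly, all windows with counts/flags, break sites).
    ``edge_exempt_bp`` defaults to the mean read length (at least one
    window): reads cannot overhang a linear contig's ends, so spanning
    coverage is depleted within about one read length of each terminus and
    sparse spanning there is not evidence of misassembly.
    """
    mean_len = mean_read_length(alignments) if alignments else 0.0
    if window_bp is None:
        window_bp = choose_window_size(mean_len, factor=window_factor)
    if edge_exempt_bp is None:
        edge_exempt_bp = max(window_bp, round(mean_len))
    lengths = {c.id: len(c.seq) for c in assembly}
    # two phase-shifted tilings: a breakpoint sitting exactly on one grid's
    # window edge is strictly interior to a window of the other grid
    windows: list[SpanWindow] = []
    for contig in assembly:
        windows.extend(tile_windows(contig, window_bp))
        if len(contig.seq) > window_bp:
            windows.extend(tile_windows(contig, window_bp, offset=window_bp // 2))
    windows = count_spanning(
        windows, alignments, min_mapq=min_mapq, contig_ids=list(lengths)
    )
    windows = flag_unsupported(
        windows, max_support=max_support, edge_exempt_bp=edge_exempt_bp,
        contig_lengths=lengths,
    )
    breaks = call_breaks(windows)
    broken = break_contigs(assembly, breaks, min_fragment_bp=min_fragment_bp)
    return broken, windows, breaks


def windows_to_bed(windows: Sequence[SpanWindow], path) -> None:
    """BED6+1: name and score mirror the spanning count, column 7 the flag."""
    with open(path, "w") as fh:
        for w in windows:
            flag = "exempt" if w.exempt else ("flagged" if w.flagged else "ok")
            fh.write(
                f"{w.interval.contig_id}\t{w.interval.start}\t{w.interval.end}"
                f"\t{w.spanning_count}\t{min(w.spanning_count, 1000)}\t+\t{flag}\n"
            )


def breaks_to_bed(breaks: Sequence[BreakSite], path) -> None:
    with open(path, "w") as fh:
        for b in breaks:
            fh.write(
                f"{b.contig_id}\t{b.position}\t{b.position + 1}"
                f"\tspanning={b.spanning_count}\n"
            )
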