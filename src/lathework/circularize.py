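"""Contig circularization: terminal-redundancy trimming and spanning closure.

Two complementary tests decide whether a contig is a closed circular genome
and locate its wrap-around (junction) point:

1. *Terminal redundancy* — an assembler that walks past the wrap-around
   point of a circular chromosome emits the same sequence twice, once at
   each contig terminus. Seeded self-alignment of the contig's prefix
   against its suffix finds the redundant copy, which is trimmed (the
   prefix copy is retained; downstream polishing re-corrects it).
2. *Spanning closure* — reads (or an externally assembled spanning contig)
   crossing the junction align in two pieces, one ending at the contig's
   end and one starting at its beginning, in tail-then-head order on the
   read. Enough such split alignments agreeing on a junction call the
   contig circular.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np

from .core import ContigRecord, GenomicInterval, ReadAlignment

__all__ = [
    "TerminalOverlap",
    "CircularizationResult",
    "detect_terminal_redundancy",
    "trim_overcircularized",
    "collect_terminal_reads",
    "test_spanning_closure",
    "finalize_circular",
    "circularize_contig",
]


@dataclass
class TerminalOverlap:
    """A redundant copy shared by a contig's prefix and suffix."""

    contig_id: str
    head_interval: GenomicInterval  # prefix copy, starts at 0
    tail_interval: GenomicInterval  # suffix copy, ends at contig length
    overlap_len: int
    identity: float


@dataclass
class CircularizationResult:
    contig_id: str
    status: str  # circular | linear | ambiguous
    trimmed_bp: int = 0
    junction_pos: Optional[int] = None
    evidence: str = "none"  # terminal_overlap | spanning_read | spanning_contig | none
    n_support_reads: int = 0

    def __post_init__(self) -> None:
        if self.status not in ("circular", "linear", "ambiguous"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "circular" and self.junction_pos is None:
            raise ValueError("circular result requires a junction position")


def detect_terminal_redundancy(
    contig: ContigRecord,
    min_overlap_bp: int = 1000,
    min_identity: float = 0.95,
    max_search_bp: int = 50000,
    k: int = 17,
) -> Optional[TerminalOverlap]:
    """Find the longest prefix/suffix redundancy by seeded self-alignment.

    Shared k-mers between the first and last ``max_search_bp`` of the contig
    propose candidate overlap lengths (one per diagonal); each candidate
    prefix-vs-suffix pair is verified with a global edlib alignment and the
    longest candidate meeting ``min_overlap_bp`` and ``min_identity`` wins.
    """
    seq = contig.seq
    L = len(seq)
    if L <= 2 * min_overlap_bp:
        raise ValueError(
            f"contig {contig.id!r} too short for min_overlap_bp={min_overlap_bp}"
        )
    search = min(max_search_bp, L // 2)
    head = seq[:search]
    tail_off = L - search
    tail = seq[tail_off:]
    # index head k-mers, scan tail
    head_pos: dict[str, list[int]] = {}
    for i in range(0, len(head) - k + 1):
        kmer = head[i : i + k]
        if "N" not in kmer:
            head_pos.setdefault(kmer, []).append(i)
    candidates: set[int] = set()
    for j in range(0, len(tail) - k + 1):
        for i in head_pos.get(tail[j : j + k], ()):
            # head position i pairs with absolute tail position tail_off + j;
            # implied overlap length v satisfies (L - v) + i = tail_off + j
            v = L - (tail_off + j - i)
            if min_overlap_bp <= v < L:
                candidates.add(v)
    best: Optional[TerminalOverlap] = None
    for v in sorted(candidates, reverse=True):
        prefix = seq[:v]
        suffix = seq[L - v :]
        res = edlib.align(prefix, suffix, mode="NW", task="distance")
        identity = 1.0 - res["editDistance"] / v
        if identity >= min_identity:
            best = TerminalOverlap(
                contig_id=contig.id,
                head_interval=GenomicInterval(contig.id, 0, v),
                tail_interval=GenomicInterval(contig.id, L - v, L),
                overlap_len=v,
                identity=identity,
            )
            break  # candidates sorted longest-first
    return best


def trim_overcircularized(
    contig: ContigRecord,
    overlap: TerminalOverlap,
    min_fragment_bp: int = 1000,
) -> ContigRecord:
    """Remove the suffix copy of a terminal redundancy and mark circular.

    The prefix (head) copy is retained and the tail copy cut: when the two
    copies disagree, later polishing re-corrects the retained copy.
    """
    if overlap.contig_id != contig.id:
        raise ValueError("overlap does not belong to this contig")
    new_len = overlap.tail_interval.start
    if new_len < min_fragment_bp:
        raise ValueError(
            f"trimming {contig.id!r} would leave {new_len} bp "
            f"(< {min_fragment_bp})"
        )
    return ContigRecord(
        id=contig.id,
        seq=contig.seq[:new_len],
        circular=True,
        provenance=(
            f"trimmed {overlap.overlap_len} bp terminal redundancy "
            f"(identity {overlap.identity:.4f}); junction at 0"
        ),
    )


def collect_terminal_reads(
    contig: ContigRecord,
    alignments: Sequence[ReadAlignment],
    terminus_bp: int = 20000,
    min_mapq: int = 10,
) -> list[str]:
    """Ids of reads with a qualifying alignment overlapping either terminus."""
    L = len(contig.seq)
    if terminus_bp >= L / 2:
        raise ValueError("terminus_bp must be < contig length / 2")
    ids: list[str] = []
    seen: set[str] = set()
    for a in alignments:
        if a.contig_id != contig.id or a.mapq < min_mapq:
            continue
        if a.ref_start < terminus_bp or a.ref_end > L - terminus_bp:
            if a.read_id not in seen:
                seen.add(a.read_id)
                ids.append(a.read_id)
    return ids


def _closure_support(
    contig_len: int,
    alns: list[ReadAlignment],
    end_window_bp: int,
) -> Optional[int]:
    """Implied junction if this read's split alignments wrap tail-to-head.

    Requires two same-strand alignments, one ending within ``end_window_bp``
    of the contig end and one starting within ``end_window_bp`` of the
    start, with the tail part preceding the head part in the read's aligned
    (stored) orientation — the orientation clips are expressed in, so the
    rule is strand-independent. Returns the implied junction (the tail
    alignment's endpoint, modulo the contig length) or None.
    """
    L = contig_len
    for tail in alns:
        if tail.ref_end < L - end_window_bp:
            continue
        for head in alns:
            if head is tail or head.strand != tail.strand:
                continue
            if head.ref_start > end_window_bp:
                continue
            t_start, _ = tail.read_interval()
            h_start, _ = head.read_interval()
            if t_start < h_start:
                return tail.ref_end % L
    return None


def test_spanning_closure(
    contig: ContigRecord,
    evidence: Sequence[ReadAlignment],
    min_support: int = 2,
    junction_tol_bp: int = 100,
    end_window_bp: int = 1000,
    evidence_kind: str = "spanning_read",
) -> CircularizationResult:
    """Decide circularity from split alignments that wrap end-to-start.

    A read supports closure when it has two same-strand split alignments,
    one reaching the contig end and one the contig start, tail before head
    on the read. The contig is circular when >= ``min_support`` reads agree
    on a junction (circular median, inter-quartile spread <=
    ``junction_tol_bp``); linear with zero support; ambiguous otherwise.
    For an externally assembled spanning contig, pass its alignments with
    ``evidence_kind='spanning_contig'`` (min_support=1 is then customary).
    """
    L = len(contig.seq)
    for a in evidence:
        if a.contig_id != contig.id:
            raise ValueError(
                f"evidence aligned to {a.contig_id!r}, not {contig.id!r}"
            )
    by_read: dict[str, list[ReadAlignment]] = {}
    for a in evidence:
        by_read.setdefault(a.read_id, []).append(a)
    junctions: list[int] = []
    for _rid, alns in sorted(by_read.items()):
        if len(alns) < 2:
            continue
        j = _closure_support(L, alns, end_window_bp)
        if j is not None:
            junctions.append(j)
    if not junctions:
        return CircularizationResult(
            contig_id=contig.id, status="linear", evidence="none",
            n_support_reads=0,
        )
    # circular statistics near 0/L: unwrap junctions close to L
    arr = np.array(junctions, dtype=float)
    ref = arr[0]
    unwrapped = np.where(np.abs(arr - ref) > L / 2, arr - np.sign(arr - ref) * L, arr)
    q1, med, q3 = np.percentile(unwrapped, [25, 50, 75])
    agree = (q3 - q1) <= junction_tol_bp
    if len(junctions) >= min_support and agree:
        return CircularizationResult(
            contig_id=contig.id,
            status="circular",
            junction_pos=int(round(med)) % L,
            evidence=evidence_kind,
            n_support_reads=len(junctions),
        )
    return CircularizationResult(
        contig_id=contig.id,
        status="ambiguous",
        evidence=evidence_kind,
        n_support_reads=len(junctions),
    )


def finalize_circular(
    contig: ContigRecord,
    result: CircularizationResult,
    rotate_to: Optional[int] = None,
) -> ContigRecord:
    """Tag a confirmed-circular contig and optionally rotate its origin."""
    if result.status != "circular":
        raise ValueError("finalize_circular requires a circular result")
    seq = contig.seq
    if rotate_to is not None:
        if not (0 <= rotate_to < len(seq)):
            raise ValueError(f"rotate_to {rotate_to} out of range")
        seq = seq[rotate_to:] + seq[:rotate_to]
    return ContigRecord(
        id=contig.id,
        seq=seq,
        circular=True,
        provenance=(
            f"circular; junction at {result.junction_pos} "
            f"({result.evidence}, {result.n_support_reads} supporting)"
            + (f"; rotated to {rotate_to}" if rotate_to else "")
        ),
    )


def circularize_contig(
    contig: ContigRecord,
    alignments: Sequence[ReadAlignment] | None = None,
    min_overlap_bp: int = 1000,
    min_identity: float = 0.95,
    max_search_bp: int = 50000,
    min_support: int = 2,
    junction_tol_bp: int = 100,
    end_window_bp: int = 1000,
) -> tuple[ContigRecord, CircularizationResult]:
    """Run both circularization methods on one contig.

    Terminal-redundancy trimming runs first (when the contig is long
    enough); if a redundancy is found the contig is trimmed and called
    circular on that evidence alone. Otherwise, spanning closure is tested
    against the supplied alignments (when given).
    """
    result = CircularizationResult(contig_id=contig.id, status="linear")
    out = contig
    if len(contig.seq) > 2 * min_overlap_bp:
        overlap = detect_terminal_redundancy(
            contig, min_overlap_bp=min_overlap_bp,
            min_identity=min_identity, max_search_bp=max_search_bp,
        )
        if overlap is not None:
            out = trim_overcircularized(contig, overlap)
            result = CircularizationResult(
                contig_id=contig.id,
                status="circular",
                trimmed_bp=overlap.overlap_len,
                junction_pos=0,
                evidence="terminal_overlap",
                n_support_reads=0,
            )
            return out, result
    if alignments:
        result = test_spanning_closure(
            contig, alignments, min_support=min_support,
            junction_tol_bp=junction_tol_bp, end_window_bp=end_window_bp,
        )
        if result.status == "circular":
            out = finalize_circular(contig, result)
    return out, result
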