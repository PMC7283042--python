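"""Segment-parallel consensus polishing with edit aggregation.

The assembly is partitioned into ~100-kb segments; per segment, aligned
short reads are downsampled to a target depth (default 50x), a base-level
pileup is built, and consensus edits (substitutions, insertions, deletions)
are called by a plurality rule. Per-segment edit lists are aggregated —
deduplicated across segment boundaries, conflicts resolved by read support —
and applied to the assembly in one pass, so results are independent of how
segments were distributed over workers. Edits sitting in or next to
homopolymer runs (the dominant nanopore error mode) are flagged.

Externally produced edit lists can be ingested and exported as VCF
(1-based, anchored-base convention for indels); the internal representation
is 0-based and anchor-free.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

from .core import (
    ContigRecord,
    GenomicInterval,
    ReadAlignment,
    ReadSet,
    parse_cigar,
    reverse_complement,
)

__all__ = [
    "Segment",
    "ConsensusEdit",
    "PileupColumn",
    "Pileup",
    "partition_segments",
    "downsample_to_depth",
    "build_pileup",
    "call_segment_edits",
    "aggregate_edits",
    "apply_edits",
    "flag_homopolymer_edits",
    "homopolymer_report",
    "polish_assembly",
    "write_edits_vcf",
    "read_edits_vcf",
]

logger = logging.getLogger(__name__)

_BASE_ORDER = "ACGT"
# byte value -> row index (A,C,G,T -> 0..3; anything else -> -1)
_BASE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASE_ORDER):
    _BASE_LUT[ord(_b)] = _i
_DEL_ROW = 4


@dataclass
class Segment:
    """One polishing work unit: a contig sub-interval plus a global index."""

    interval: GenomicInterval
    index: int


@dataclass
class ConsensusEdit:
    """A positioned correction on the input assembly (0-based, anchor-free).

    ``ref_allele`` empty = insertion before ``pos``; ``alt_allele`` empty =
    deletion of ``ref_allele`` at ``pos``.
    """

    contig_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    depth: int = 0
    alt_support: int = 0
    homopolymer: bool = False

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele must differ from alt_allele")
        if self.alt_support > self.depth:
            raise ValueError("alt_support cannot exceed depth")

    @property
    def end(self) -> int:
        return self.pos + len(self.ref_allele)

    def key(self) -> tuple:
        return (self.contig_id, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class PileupColumn:
    contig_id: str
    pos: int
    base_counts: dict[str, int]
    insertion_counts: dict[str, int]


@dataclass
class Pileup:
    """Array-backed pileup over one segment.

    ``counts`` has shape (5, segment length): rows A, C, G, T, del.
    ``insertions`` maps an absolute reference position to a Counter of
    sequences inserted immediately after it.
    """

    contig_id: str
    start: int
    end: int
    counts: np.ndarray
    insertions: dict[int, Counter] = field(default_factory=dict)

    def __len__(self) -> int:
        return self.end - self.start

    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def column(self, pos: int) -> PileupColumn:
        i = pos - self.start
        if not (0 <= i < len(self)):
            raise IndexError(f"position {pos} outside pileup")
        base_counts = {
            b: int(self.counts[j, i]) for j, b in enumerate(_BASE_ORDER)
        }
        base_counts["del"] = int(self.counts[_DEL_ROW, i])
        return PileupColumn(
            contig_id=self.contig_id,
            pos=pos,
            base_counts=base_counts,
            insertion_counts=dict(self.insertions.get(pos, {})),
        )

    def columns(self) -> Iterator[PileupColumn]:
        for pos in range(self.start, self.end):
            yield self.column(pos)


def partition_segments(
    assembly: Sequence[ContigRecord], segment_bp: int = 100_000
) -> list[Segment]:
    """Tile each contig into segments; a trailing remainder shorter than
    segment_bp/2 is merged into the previous segment."""
    if segment_bp < 1:
        raise ValueError("segment_bp must be >= 1")
    segments: list[Segment] = []
    index = 0
    for contig in assembly:
        L = len(contig.seq)
        edges = list(range(0, L, segment_bp)) + [L]
        if len(edges) > 2 and edges[-1] - edges[-2] < segment_bp / 2:
            del edges[-2]
        for s, e in zip(edges, edges[1:]):
            segments.append(
                Segment(interval=GenomicInterval(contig.id, s, e), index=index)
            )
            index += 1
    return segments


def _keep_fraction(seed: int, segment_index: int, read_id: str, occ: int) -> float:
    digest = hashlib.blake2b(
        f"{seed}|{segment_index}|{read_id}|{occ}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") / 2**64


def downsample_to_depth(
    alignments: Sequence[ReadAlignment],
    segment: Segment,
    target_depth: int = 50,
    seed: int = 0,
) -> list[ReadAlignment]:
    """Seeded uniform downsampling of segment-overlapping alignments to a
    target mean depth.

    Each alignment is kept with probability min(1, target / observed mean
    depth), decided by a stable hash of (seed, segment index, read id), so
    the subset is deterministic and independent of input order.
    """
    if target_depth < 1:
        raise ValueError("target_depth must be >= 1")
    iv = segment.interval
    overlapping = []
    covered = 0
    for a in alignments:
        if a.contig_id != iv.contig_id:
            continue
        ov = min(a.ref_end, iv.end) - max(a.ref_start, iv.start)
        if ov > 0:
            overlapping.append(a)
            covered += ov
    observed = covered / len(iv)
    if observed <= target_depth:
        return overlapping
    p = target_depth / observed
    occ: Counter = Counter()
    kept = []
    for a in overlapping:
        n = occ[a.read_id]
        occ[a.read_id] += 1
        if _keep_fraction(seed, segment.index, a.read_id, n) < p:
            kept.append(a)
    return kept


def build_pileup(
    segment: Segment,
    alignments: Sequence[ReadAlignment],
    reads: ReadSet,
    min_base_q: int = 0,
) -> Pileup:
    """Cigar-walk pileup over one segment.

    Bases below ``min_base_q`` are excluded from base counts. Insertions are
    attributed to the reference position they immediately follow.
    """
    iv = segment.interval
    s, e = iv.start, iv.end
    counts = np.zeros((5, e - s), dtype=np.int32)
    insertions: dict[int, Counter] = {}
    seqs: dict[str, tuple[str, Optional[str]]] = {
        rid: (seq, qual) for rid, seq, qual in reads
    }
    for a in alignments:
        if a.contig_id != iv.contig_id or a.ref_end <= s or a.ref_start >= e:
            continue
        if a.read_id not in seqs:
            raise ValueError(f"no sequence for aligned read {a.read_id!r}")
        seq, qual = seqs[a.read_id]
        if a.strand == "-":
            seq = reverse_complement(seq)
            qual = qual[::-1] if qual else None
        obytes = np.frombuffer(seq.encode(), dtype=np.uint8)
        oqual = (
            np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int16) - 33
            if qual is not None
            else None
        )
        cigar = a.cigar or f"{a.ref_span}M"
        _walk_cigar(
            a, cigar, obytes, oqual, s, e, counts, insertions, min_base_q
        )
    return Pileup(
        contig_id=iv.contig_id, start=s, end=e, counts=counts,
        insertions=insertions,
    )


def _walk_cigar(a, cigar, obytes, oqual, s, e, counts, insertions, min_base_q):
    qpos = 0
    rpos = a.ref_start
    ops = parse_cigar(cigar)
    consumed = sum(n for n, op in ops if op in "MIS=X")
    if len(obytes) and consumed and consumed != len(obytes):
        raise ValueError(
            f"cigar {cigar!r} inconsistent with read {a.read_id!r} length "
            f"({consumed} vs {len(obytes)})"
        )
    for n, op in ops:
        if op in "M=X":
            ov0, ov1 = max(rpos, s), min(rpos + n, e)
            if ov1 > ov0:
                qoff = qpos + (ov0 - rpos)
                chunk = obytes[qoff : qoff + (ov1 - ov0)]
                idx = _BASE_LUT[chunk]
                pos = np.arange(ov0 - s, ov1 - s)
                valid = idx >= 0
                if oqual is not None and min_base_q > 0:
                    valid &= oqual[qoff : qoff + (ov1 - ov0)] >= min_base_q
                np.add.at(counts, (idx[valid], pos[valid]), 1)
            qpos += n
            rpos += n
        elif op == "I":
            anchor = rpos - 1
            if s <= anchor < e and rpos > 0:
                ok = True
                if oqual is not None and min_base_q > 0:
                    ok = bool((oqual[qpos : qpos + n] >= min_base_q).all())
                if ok:
                    ins = obytes[qpos : qpos + n].tobytes().decode()
                    insertions.setdefault(anchor, Counter())[ins] += 1
            qpos += n
        elif op in "DN":
            ov0, ov1 = max(rpos, s), min(rpos + n, e)
            if ov1 > ov0:
                counts[_DEL_ROW, ov0 - s : ov1 - s] += 1
            rpos += n
        elif op in "SH":
            if op == "S":
                qpos += n
        else:  # P consumes nothing
            pass


def call_segment_edits(
    segment: Segment,
    pileup: Pileup,
    ref: ContigRecord,
    min_depth: int = 5,
    min_alt_frac: float = 0.7,
) -> list[ConsensusEdit]:
    """Plurality edit calling over one segment's pileup.

    At each column with depth >= ``min_depth``, emit a substitution when the
    plurality non-reference base reaches ``min_alt_frac`` of the depth, a
    deletion when the deletion fraction does, and an insertion when one
    inserted sequence does; ties break toward the reference (no edit).
    """
    iv = segment.interval
    s, e = iv.start, iv.end
    refbytes = np.frombuffer(ref.seq[s:e].encode(), dtype=np.uint8)
    refidx = _BASE_LUT[refbytes]
    counts = pileup.counts
    depth = counts.sum(axis=0)
    cols = np.arange(e - s)
    known = refidx >= 0
    refcount = np.zeros(e - s, dtype=np.int64)
    refcount[known] = counts[refidx[known], cols[known]]
    masked = counts[:4].astype(np.int64).copy()
    masked[refidx[known], cols[known]] = -1
    alt_idx = masked.argmax(axis=0)
    alt_count = masked.max(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok_depth = depth >= max(1, min_depth)
        sub_mask = (
            ok_depth & known
            & (alt_count >= min_alt_frac * depth)
            & (alt_count > refcount)
        )
        del_count = counts[_DEL_ROW].astype(np.int64)
        del_mask = (
            ok_depth & known
            & (del_count >= min_alt_frac * depth)
            & (del_count > refcount)
        )
    edits: list[ConsensusEdit] = []
    for i in np.nonzero(sub_mask | del_mask)[0]:
        pos = s + int(i)
        refbase = ref.seq[pos]
        if del_mask[i] and (not sub_mask[i] or del_count[i] >= alt_count[i]):
            edits.append(
                ConsensusEdit(
                    iv.contig_id, pos, refbase, "",
                    depth=int(depth[i]), alt_support=int(del_count[i]),
                )
            )
        else:
            edits.append(
                ConsensusEdit(
                    iv.contig_id, pos, refbase, _BASE_ORDER[alt_idx[i]],
                    depth=int(depth[i]), alt_support=int(alt_count[i]),
                )
            )
    for anchor in sorted(pileup.insertions):
        if not (s <= anchor < e):
            continue
        i = anchor - s
        d = int(depth[i])
        if d < min_depth:
            continue
        ins, cnt = sorted(
            pileup.insertions[anchor].items(), key=lambda kv: (-kv[1], kv[0])
        )[0]
        if cnt >= min_alt_frac * d and 2 * cnt > d:
            edits.append(
                ConsensusEdit(
                    iv.contig_id, anchor + 1, "", ins,
                    depth=d, alt_support=cnt,
                )
            )
    edits.sort(key=lambda ed: ed.pos)
    return edits


def left_align_edit(edit: ConsensusEdit, seq: str) -> tuple:
    """Canonical (contig, pos, ref, alt) with 1-bp indels left-aligned.

    An insertion or deletion inside a repeat run has several equivalent
    placements; shifting to the leftmost one gives a canonical key for
    comparing edit sets (the usual VCF normalization convention).
    """
    pos, ref, alt = edit.pos, edit.ref_allele, edit.alt_allele
    if len(ref) == 1 and not alt:  # deletion
        while pos > 0 and seq[pos - 1] == ref:
            pos -= 1
    elif len(alt) == 1 and not ref:  # insertion
        while pos > 0 and seq[pos - 1] == alt:
            pos -= 1
    return (edit.contig_id, pos, ref, alt)


def _conflicts(a: ConsensusEdit, b: ConsensusEdit) -> bool:
    if a.contig_id != b.contig_id:
        return False
    if not a.ref_allele and not b.ref_allele:  # two insertions
        return a.pos == b.pos
    if not a.ref_allele:  # a is an insertion: conflict if strictly inside b
        return b.pos < a.pos < b.end
    if not b.ref_allele:
        return a.pos < b.pos < a.end
    return a.pos < b.end and b.pos < a.end


def aggregate_edits(
    per_segment_edits: Sequence[Sequence[ConsensusEdit]],
) -> list[ConsensusEdit]:
    """Merge per-segment edit lists into one consistent, sorted list.

    Identical edits reported by adjacent segments are deduplicated (keeping
    the max support); overlapping conflicting edits are resolved in favor of
    higher alt support, ties in favor of the lower position, and dropped
    edits are logged.
    """
    best: dict[tuple, ConsensusEdit] = {}
    for seg_edits in per_segment_edits:
        for ed in seg_edits:
            k = ed.key()
            cur = best.get(k)
            if cur is None or ed.alt_support > cur.alt_support:
                best[k] = ed
    pool = sorted(
        best.values(), key=lambda ed: (ed.contig_id, ed.pos, ed.end)
    )
    kept: list[ConsensusEdit] = []
    for ed in pool:
        winner = ed
        while kept and _conflicts(kept[-1], winner):
            prev = kept.pop()
            if winner.alt_support > prev.alt_support:
                logger.warning("dropping conflicting edit %s (kept %s)",
                               prev.key(), winner.key())
            else:  # tie resolves to the lower position, i.e. the earlier edit
                logger.warning("dropping conflicting edit %s (kept %s)",
                               winner.key(), prev.key())
                winner = prev
        kept.append(winner)
    return kept


def apply_edits(
    assembly: Sequence[ContigRecord], edits: Sequence[ConsensusEdit]
) -> list[ContigRecord]:
    """Apply non-overlapping edits, highest position first per contig.

    The output length equals the input length plus the signed sum of edit
    length deltas; applying an empty edit list is the identity.
    """
    by_contig: dict[str, list[ConsensusEdit]] = {}
    known = {c.id for c in assembly}
    for ed in edits:
        if ed.contig_id not in known:
            raise ValueError(f"edit on unknown contig {ed.contig_id!r}")
        by_contig.setdefault(ed.contig_id, []).append(ed)
    out: list[ContigRecord] = []
    for contig in assembly:
        eds = sorted(
            by_contig.get(contig.id, []), key=lambda ed: (ed.pos, ed.end)
        )
        for prev, nxt in zip(eds, eds[1:]):
            if _conflicts(prev, nxt):
                raise ValueError(
                    f"overlapping edits at {contig.id}:{prev.pos} and "
                    f"{contig.id}:{nxt.pos}"
                )
        seq = contig.seq
        for ed in reversed(eds):
            if ed.end > len(seq):
                raise ValueError(
                    f"edit at {contig.id}:{ed.pos} out of bounds"
                )
            if seq[ed.pos : ed.end] != ed.ref_allele:
                raise ValueError(
                    f"edit at {contig.id}:{ed.pos} does not match the "
                    f"reference ({seq[ed.pos:ed.end]!r} != {ed.ref_allele!r})"
                )
            seq = seq[: ed.pos] + ed.alt_allele + seq[ed.end :]
        if eds:
            out.append(
                ContigRecord(
                    id=contig.id, seq=seq, circular=contig.circular,
                    provenance=(contig.provenance + "; " if contig.provenance
                                else "") + f"polished ({len(eds)} edits)",
                )
            )
        else:
            out.append(contig)
    return out


def flag_homopolymer_edits(
    edits: Sequence[ConsensusEdit],
    ref: Sequence[ContigRecord],
    min_run: int = 4,
) -> list[ConsensusEdit]:
    """Flag edits overlapping or immediately adjacent (±1 bp) to a reference
    homopolymer run of length >= ``min_run``."""
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    seqs = {c.id: c.seq for c in ref}
    out = []
    for ed in edits:
        seq = seqs[ed.contig_id]
        lo = max(0, ed.pos - min_run - 1)
        hi = min(len(seq), ed.end + min_run + 1)
        flag = False
        run_start = lo
        for i in range(lo + 1, hi + 1):
            if i == hi or seq[i] != seq[run_start]:
                if i - run_start >= min_run:
                    # run [run_start, i) must touch the edit's ±1 bp halo
                    if run_start < ed.end + 1 and i > ed.pos - 1:
                        flag = True
                        break
                run_start = i
        out.append(replace(ed, homopolymer=flag))
    return out


def homopolymer_report(edits: Sequence[ConsensusEdit]):
    """Per-contig edit and homopolymer-edit counts as a DataFrame."""
    import pandas as pd

    rows: dict[str, list[int]] = {}
    for ed in edits:
        rows.setdefault(ed.contig_id, [0, 0])
        rows[ed.contig_id][0] += 1
        rows[ed.contig_id][1] += int(ed.homopolymer)
    return pd.DataFrame(
        [
            {"contig": cid, "n_edits": n, "n_homopolymer_edits": h}
            for cid, (n, h) in sorted(rows.items())
        ],
        columns=["contig", "n_edits", "n_homopolymer_edits"],
    )


@dataclass
class PolishResult:
    polished: list[ContigRecord]
    edits: list[ConsensusEdit]
    segments: list[Segment]


def polish_assembly(
    assembly: Sequence[ContigRecord],
    alignments: Sequence[ReadAlignment],
    reads: ReadSet,
    segment_bp: int = 100_000,
    target_depth: int = 50,
    seed: int = 0,
    min_depth: int = 5,
    min_alt_frac: float = 0.7,
    min_base_q: int = 0,
    min_homopolymer_run: int = 4,
    external_edits: Optional[Sequence[ConsensusEdit]] = None,
    segment_order: Optional[Sequence[int]] = None,
) -> PolishResult:
    """Full polishing pass: segment, downsample, call, aggregate, apply.

    ``segment_order`` permutes segment processing (results are invariant to
    it — the contract that makes the segment-parallel scheme sound). When
    ``external_edits`` is given, edit calling is skipped and those edits are
    aggregated/applied instead.
    """
    segments = partition_segments(assembly, segment_bp=segment_bp)
    refs = {c.id: c for c in assembly}
    if external_edits is not None:
        per_segment = [list(external_edits)]
    else:
        order = list(segment_order) if segment_order is not None else range(
            len(segments)
        )
        per_segment = []
        for i in order:
            seg = segments[i]
            subset = downsample_to_depth(
                alignments, seg, target_depth=target_depth, seed=seed
            )
            pileup = build_pileup(seg, subset, reads, min_base_q=min_base_q)
            per_segment.append(
                call_segment_edits(
                    seg, pileup, refs[seg.interval.contig_id],
                    min_depth=min_depth, min_alt_frac=min_alt_frac,
                )
            )
    edits = aggregate_edits(per_segment)
    edits = flag_homopolymer_edits(edits, assembly, min_run=min_homopolymer_run)
    polished = apply_edits(assembly, edits)
    return PolishResult(polished=polished, edits=edits, segments=segments)


# ---------------------------------------------------------------------------
# VCF interchange (1-based, anchored-base convention for indels)
# ---------------------------------------------------------------------------


def write_edits_vcf(
    edits: Sequence[ConsensusEdit],
    assembly: Sequence[ContigRecord],
    path,
) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("source", "lathework-polish")
    for c in assembly:
        header.contigs.add(c.id, length=len(c.seq))
    header.info.add("DP", 1, "Integer", "Pileup depth at the edit")
    header.info.add("AO", 1, "Integer", "Reads supporting the edit")
    header.info.add("HP", 0, "Flag", "Edit in or adjacent to a homopolymer")
    seqs = {c.id: c.seq for c in assembly}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for ed in sorted(edits, key=lambda e: (e.contig_id, e.pos)):
            seq = seqs[ed.contig_id]
            ref, alt, start = ed.ref_allele, ed.alt_allele, ed.pos
            if not ref or not alt:  # indel: anchor on the previous base
                if start > 0:
                    anchor = seq[start - 1]
                    ref, alt, start = anchor + ref, anchor + alt, start - 1
                else:  # anchor on the following base instead
                    anchor = seq[ed.end]
                    ref, alt = ref + anchor, alt + anchor
            rec = vcf.new_record(
                contig=ed.contig_id,
                start=start,
                stop=start + len(ref),
                alleles=(ref, alt),
            )
            rec.info["DP"] = ed.depth
            rec.info["AO"] = ed.alt_support
            if ed.homopolymer:
                rec.info["HP"] = True
            vcf.write(rec)


def read_edits_vcf(path, assembly: Sequence[ContigRecord]) -> list[ConsensusEdit]:
    import pysam

    known = {c.id for c in assembly}
    edits: list[ConsensusEdit] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.contig not in known:
                raise ValueError(f"VCF contig {rec.contig!r} not in assembly")
            ref = rec.ref
            alt = rec.alts[0] if rec.alts else ""
            start = rec.start
            # strip the anchored-base padding back to the anchor-free form
            while ref and alt and ref[0] == alt[0]:
                ref, alt, start = ref[1:], alt[1:], start + 1
            while ref and alt and ref[-1] == alt[-1]:
                ref, alt = ref[:-1], alt[:-1]
            info = rec.info
            edits.append(
                ConsensusEdit(
                    contig_id=rec.contig,
                    pos=start,
                    ref_allele=ref,
                    alt_allele=alt,
                    depth=int(info.get("DP", 0)),
                    alt_support=int(info.get("AO", 0)),
                    homopolymer=bool(info.get("HP", False)),
                )
            )
    return edits
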