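"""Internal k-mer-anchored read mapper for synthetic and low-error reads.

Exact k-mer anchoring locates candidate loci; edlib provides the banded
base-level alignment. Reads that align end-to-end at acceptable error get a
single full-length alignment; reads whose parts map to different loci
(chimeric reads, reads crossing a circular wrap-around) get split alignments
with one-sided clips. This mapper exists so that every downstream stage is
testable without an external aligner; real nanopore data should arrive
pre-aligned as SAM/BAM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib

from .core import ContigRecord, ReadAlignment, ReadSet, reverse_complement

__all__ = ["map_reads_anchored", "KmerIndex"]


class KmerIndex:
    """Exact k-mer position index over a set of contigs."""

    def __init__(self, contigs: Sequence[ContigRecord], k: int = 17):
        if k < 11:
            raise ValueError("k must be >= 11")
        self.k = k
        self.contigs = list(contigs)
        self.seqs = {c.id: c.seq for c in contigs}
        index: dict[str, list[tuple[int, int]]] = {}
        for ci, contig in enumerate(self.contigs):
            seq = contig.seq
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((ci, pos))
        self.index = index

    def hits(self, seq: str, step: int) -> list[tuple[int, int, int]]:
        """(query_pos, contig_index, ref_pos) for sampled exact k-mer matches."""
        k = self.k
        out = []
        get = self.index.get
        for qpos in range(0, len(seq) - k + 1, step):
            for ci, rpos in get(seq[qpos : qpos + k], ()):
                out.append((qpos, ci, rpos))
        return out


@dataclass
class _Cluster:
    ci: int
    strand: str
    qs: int
    qe: int
    rs: int
    re: int
    n_hits: int


def _cluster_hits(
    hits: list[tuple[int, int, int]], strand: str, k: int, band: int
) -> list[_Cluster]:
    """Group anchors by (contig, diagonal band) into colinear clusters."""
    by_key: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for qpos, ci, rpos in hits:
        diag = rpos - qpos
        by_key.setdefault((ci, diag // band), []).append((qpos, rpos))
    # merge adjacent diagonal buckets of the same contig
    merged: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for (ci, b), pts in sorted(by_key.items()):
        if (ci, b - 1) in merged:
            merged[(ci, b - 1)].extend(pts)
            merged[(ci, b)] = merged[(ci, b - 1)]
        else:
            merged[(ci, b)] = pts
    clusters = []
    seen_ids = set()
    for (ci, _b), pts in merged.items():
        if id(pts) in seen_ids:
            continue
        seen_ids.add(id(pts))
        qpos = [p[0] for p in pts]
        rpos = [p[1] for p in pts]
        clusters.append(
            _Cluster(
                ci=ci,
                strand=strand,
                qs=min(qpos),
                qe=max(qpos) + k,
                rs=min(rpos),
                re=max(rpos) + k,
                n_hits=len(pts),
            )
        )
    return clusters


def _xdrop_extend_right(query: str, target: str, drop: int = 12) -> int:
    """Bases of matched extension (query vs target, same length walk)."""
    best = score = best_i = 0
    for i in range(min(len(query), len(target))):
        score += 1 if query[i] == target[i] else -3
        if score > best:
            best, best_i = score, i + 1
        if best - score > drop:
            break
    return best_i


def _edlib_blocks(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _EXT_CIGAR_RE.findall(cigar)]


_EXT_CIGAR_RE = __import__("re").compile(r"(\d+)([=XIDM])")


def _blocks_to_sam(blocks: list[tuple[int, str]]) -> str:
    """Collapse =/X runs into SAM-style M runs."""
    out: list[tuple[int, str]] = []
    for n, op in blocks:
        op = "M" if op in "=XM" else op
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + n, op)
        else:
            out.append((n, op))
    return "".join(f"{n}{op}" for n, op in out)


def _trim_local(
    blocks: list[tuple[int, str]], match: int = 2, penalty: int = 4
) -> Optional[tuple[int, int]]:
    """Max-scoring contiguous block range (Kadane): terminal stretches that
    score negatively — foreign sequence past a junction, for instance — are
    trimmed into soft clips, the way a production aligner would clip them."""
    best_score = 0
    best: Optional[tuple[int, int]] = None
    cur = 0
    cur_start = 0
    for i, (n, op) in enumerate(blocks):
        s = match * n if op in "=M" else -penalty * n
        if cur <= 0:
            cur, cur_start = s, i
        else:
            cur += s
        if cur > best_score:
            best_score, best = cur, (cur_start, i)
    return best


def _clip_alignment(cigar: str) -> Optional[tuple[int, int, int, int, int, str]]:
    """Trim an extended cigar to its best local stretch.

    Returns (query_offset, ref_offset, query_len, ref_len, edit_distance,
    sam_cigar) of the kept segment, or None if nothing aligns positively.
    """
    blocks = _edlib_blocks(cigar)
    rng = _trim_local(blocks)
    if rng is None:
        return None
    i0, i1 = rng
    qoff = sum(n for n, op in blocks[:i0] if op in "=XIM")
    roff = sum(n for n, op in blocks[:i0] if op in "=XDM")
    kept = blocks[i0 : i1 + 1]
    qlen = sum(n for n, op in kept if op in "=XIM")
    rlen = sum(n for n, op in kept if op in "=XDM")
    ed = sum(n for n, op in kept if op in "XID")
    return qoff, roff, qlen, rlen, ed, _blocks_to_sam(kept)


def map_reads_anchored(
    reads: ReadSet,
    contigs: Sequence[ContigRecord],
    k: int = 17,
    max_error_frac: float = 0.1,
    step: Optional[int] = None,
    index: Optional[KmerIndex] = None,
) -> list[ReadAlignment]:
    """Map reads to contigs by exact-k-mer anchoring + edlib extension.

    Error-free reads simulated from a contig receive exactly one primary
    alignment at their true origin interval; chimeric and wrap-around reads
    receive split alignments with clips at the junction. Reads that fail to
    anchor are reported unaligned (omitted).
    """
    if index is None:
        index = KmerIndex(contigs, k=k)
    k = index.k
    alignments: list[ReadAlignment] = []
    for rid, seq, _qual in reads:
        alns = _map_one(rid, seq, index, max_error_frac, step)
        alignments.extend(alns)
    return alignments


def _map_one(
    rid: str,
    seq: str,
    index: KmerIndex,
    max_error_frac: float,
    step: Optional[int],
) -> list[ReadAlignment]:
    L = len(seq)
    k = index.k
    if L < k:
        return []
    if step is None:
        step = max(1, min(50, L // 40))
    band = max(32, int(max_error_frac * L) + 8)
    clusters: list[_Cluster] = []
    oriented = {"+": seq, "-": reverse_complement(seq)}
    all_hits = {s: index.hits(o, step) for s, o in oriented.items()}
    if not any(all_hits.values()) and step > 1:
        dense = max(1, k // 2)
        all_hits = {s: index.hits(o, dense) for s, o in oriented.items()}
    for strand, hits in all_hits.items():
        clusters.extend(_cluster_hits(hits, strand, k, band))
    if not clusters:
        return []
    clusters.sort(key=lambda c: (-(c.qe - c.qs), -c.n_hits, c.ci, c.rs))

    # 1) try a full-length alignment at the best cluster's locus
    best = clusters[0]
    full = _try_full(rid, oriented[best.strand], best, index, max_error_frac)
    if full is not None:
        return [full]

    # 2) split mapping: per-cluster partial alignments
    candidates: list[tuple[float, ReadAlignment]] = []
    for cl in clusters:
        aln = _try_partial(rid, oriented[cl.strand], cl, index, max_error_frac)
        if aln is not None:
            candidates.append(aln)
    if not candidates:
        return []
    # drop near-duplicate read intervals, keeping the better-scoring one
    candidates.sort(key=lambda t: (t[0], -(t[1].ref_span)))
    kept: list[tuple[float, ReadAlignment]] = []
    for frac, aln in candidates:
        qs, qe = aln.read_interval()
        dup = False
        for _, other in kept:
            os_, oe = other.read_interval()
            overlap = min(qe, oe) - max(qs, os_)
            if overlap > 0.5 * min(qe - qs, oe - os_):
                dup = True
                break
        if not dup:
            kept.append((frac, aln))
    kept.sort(key=lambda t: -(t[1].query_aligned_length))
    out = []
    for i, (_frac, aln) in enumerate(kept):
        aln.is_primary = i == 0
        out.append(aln)
    return out


def _try_full(
    rid: str, oseq: str, cl: _Cluster, index: KmerIndex, max_error_frac: float
) -> Optional[ReadAlignment]:
    contig = index.contigs[cl.ci]
    ref = contig.seq
    L = len(oseq)
    # exact-match fast path along the anchor diagonal
    diag = cl.rs - cl.qs
    if 0 <= diag and diag + L <= len(ref) and ref[diag : diag + L] == oseq:
        return ReadAlignment(
            read_id=rid, contig_id=contig.id, ref_start=diag,
            ref_end=diag + L, strand=cl.strand, mapq=60, is_primary=True,
            cigar=f"{L}M", left_clip=0, right_clip=0,
        )
    pad = int(max_error_frac * L) + 16
    w_start = max(0, cl.rs - cl.qs - pad)
    w_end = min(len(ref), cl.re + (L - cl.qe) + pad)
    if w_end - w_start < L:
        return None  # read cannot fit inside the contig here
    window = ref[w_start:w_end]
    # narrow band first: near-exact reads are the common case
    k_full = int(max_error_frac * L) + 1
    res = edlib.align(oseq, window, mode="HW", task="path",
                      k=min(32, k_full))
    if res["editDistance"] < 0 and k_full > 32:
        res = edlib.align(oseq, window, mode="HW", task="path", k=k_full)
    if res["editDistance"] < 0:
        return None
    loc0 = res["locations"][0][0]
    clip = _clip_alignment(res["cigar"])
    if clip is None:
        return None
    qoff, roff, qlen, rlen, ed, sam = clip
    if ed > max_error_frac * qlen or qlen < 0.9 * L:
        return None  # too erroneous, or mostly clipped: go via split mapping
    left, right = qoff, L - qoff - qlen
    cigar = (f"{left}S" if left else "") + sam + (f"{right}S" if right else "")
    ref_start = w_start + loc0 + roff
    return ReadAlignment(
        read_id=rid,
        contig_id=contig.id,
        ref_start=ref_start,
        ref_end=ref_start + rlen,
        strand=cl.strand,
        mapq=60,
        is_primary=True,
        cigar=cigar,
        left_clip=left,
        right_clip=right,
    )


def _try_partial(
    rid: str, oseq: str, cl: _Cluster, index: KmerIndex, max_error_frac: float
) -> Optional[tuple[float, ReadAlignment]]:
    contig = index.contigs[cl.ci]
    ref = contig.seq
    # X-drop extension outward from the anchored block
    ext_r = _xdrop_extend_right(oseq[cl.qe :], ref[cl.re :])
    ext_l = _xdrop_extend_right(
        oseq[: cl.qs][::-1], ref[: cl.rs][::-1]
    )
    qs, qe = cl.qs - ext_l, cl.qe + ext_r
    rs, re_ = cl.rs - ext_l, cl.re + ext_r
    if qe - qs < index.k:
        return None
    segment = oseq[qs:qe]
    res = edlib.align(segment, ref[rs:re_], mode="NW", task="path")
    clip = _clip_alignment(res["cigar"])
    if clip is None:
        return None
    qoff, roff, qlen, rlen, ed, sam = clip
    frac = ed / max(1, qlen)
    if frac > max_error_frac or qlen < index.k:
        return None
    left, right = qs + qoff, len(oseq) - (qs + qoff + qlen)
    cigar = (f"{left}S" if left else "") + sam + (
        f"{right}S" if right else ""
    )
    aln = ReadAlignment(
        read_id=rid,
        contig_id=contig.id,
        ref_start=rs + roff,
        ref_end=rs + roff + rlen,
        strand=cl.strand,
        mapq=60,
        is_primary=False,
        cigar=cigar,
        left_clip=left,
        right_clip=right,
    )
    return frac, aln
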