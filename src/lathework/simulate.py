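"""Synthetic genomes, reads and defective assemblies with truth records.

Every generator is a pure function of its seed and parameters, and every
fixture carries a machine-readable truth record sufficient to score the
module that consumes it: chimeric contigs know their junction, mutated
drafts know the corrections that restore the original, simulated reads know
their origin intervals. Read lengths follow a lognormal model (mean ~5 kb by
default, matching the scale of nanopore metagenome libraries); sequencing
errors are uniform substitutions/indels, which is deliberately simpler than
the homopolymer-biased error spectrum of real nanopore data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import ContigRecord, ReadAlignment, ReadSet, reverse_complement
from .polish import ConsensusEdit

__all__ = [
    "GenomeSpec",
    "ReadSimParams",
    "TruthRecord",
    "SimulatedReads",
    "make_genome",
    "simulate_long_reads",
    "simulate_short_reads",
    "plant_chimera",
    "plant_terminal_redundancy",
    "mutate_assembly",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class GenomeSpec:
    """Parameters for one synthetic genome."""

    length: int
    gc: float = 0.5
    circular: bool = False
    repeats: list[tuple] = field(default_factory=list)  # (unit_len, copies[, positions])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1000:
            raise ValueError("genome length must be >= 1000")
        if not (0 < self.gc < 1):
            raise ValueError("gc must be in (0, 1)")


@dataclass
class ReadSimParams:
    """Long-read simulation parameters (lognormal lengths, uniform errors)."""

    depth: float = 30.0
    mean_len: int = 5000
    sigma: float = 0.35
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    chimera_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate", "chimera_rate"):
            r = getattr(self, name)
            if not (0 <= r <= 0.3):
                raise ValueError(f"{name} must be in [0, 0.3]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass
class TruthRecord:
    """Ground truth for one simulated read or constructed contig."""

    name: str
    event: str  # normal | chimera | planted_break | terminal_redundancy | planted_edit
    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)


@dataclass
class SimulatedReads:
    reads: ReadSet
    truth: list[TruthRecord]

    def truth_alignments(self) -> list[ReadAlignment]:
        """Origin intervals as alignments (exact only for error-free reads)."""
        alns = []
        for rec in self.truth:
            offset = 0
            parts = rec.intervals
            total = sum(e - s for _, s, e, _ in parts)
            for i, (contig, start, end, strand) in enumerate(parts):
                span = end - start
                # clips are expressed in the aligned (stored) orientation,
                # as in SAM; intervals here are in native read order
                left = offset if strand == "+" else total - offset - span
                alns.append(
                    ReadAlignment(
                        read_id=rec.name,
                        contig_id=contig,
                        ref_start=start,
                        ref_end=end,
                        strand=strand,
                        mapq=60,
                        is_primary=i == 0,
                        cigar=f"{span}M",
                        left_clip=left,
                        right_clip=total - left - span,
                    )
                )
                offset += span
        return alns


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    at = (1 - gc) / 2
    g = gc / 2
    return rng.choice(_BASES, size=length, p=[at, g, g, at])


def make_genome(spec: GenomeSpec) -> tuple[ContigRecord, TruthRecord]:
    """Generate one seeded random genome, optionally with exact repeats."""
    rng = np.random.default_rng(spec.seed)
    arr = _random_seq(rng, spec.length, spec.gc)
    truth = TruthRecord(name=f"genome_seed{spec.seed}", event="normal")
    occupied: list[tuple[int, int]] = []
    for rep in spec.repeats:
        unit_len, copies = rep[0], rep[1]
        positions = list(rep[2]) if len(rep) > 2 and rep[2] else None
        unit = _random_seq(rng, unit_len, spec.gc)
        if positions is None:
            positions = []
            for _ in range(copies):
                for _attempt in range(1000):
                    p = int(rng.integers(0, spec.length - unit_len))
                    if all(p + unit_len <= s or p >= e for s, e in occupied):
                        positions.append(p)
                        occupied.append((p, p + unit_len))
                        break
                else:
                    raise ValueError("could not place repeat copies")
        else:
            for p in positions:
                if any(p < e and p + unit_len > s for s, e in occupied):
                    raise ValueError(f"overlapping repeat placement at {p}")
                occupied.append((p, p + unit_len))
        for p in positions:
            arr[p : p + unit_len] = unit
            truth.intervals.append((truth.name, p, p + unit_len, "+"))
    contig = ContigRecord(
        id=truth.name,
        seq=arr.tobytes().decode(),
        circular=spec.circular,
    )
    return contig, truth


def _mutate_seq(
    seq: str, sub_rate: float, ins_rate: float, del_rate: float,
    rng: np.random.Generator,
) -> str:
    """Apply uniform per-base substitutions and 1-bp indels."""
    if sub_rate == ins_rate == del_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1")
    n = len(arr)
    out = []
    u = rng.random(n)
    sub_mask = u < sub_rate
    del_mask = (u >= sub_rate) & (u < sub_rate + del_rate)
    ins_mask = rng.random(n) < ins_rate
    subs = rng.choice(_BASES, size=int(sub_mask.sum()))
    inss = rng.choice(_BASES, size=int(ins_mask.sum()))
    si = ii = 0
    for i in range(n):
        if ins_mask[i]:
            out.append(inss[ii])
            ii += 1
        if del_mask[i]:
            continue
        if sub_mask[i]:
            out.append(subs[si])
            si += 1
        else:
            out.append(arr[i])
    return b"".join(out).decode()


def simulate_long_reads(
    genome: ContigRecord, params: ReadSimParams
) -> SimulatedReads:
    """Simulate long reads to the requested depth with truth origins.

    Circular genomes are sampled with wrap-around (reads may cross position
    0, recorded as two origin intervals). A fraction ``chimera_rate`` of
    reads joins two independently placed fragments on independent strands.
    """
    rng = np.random.default_rng(params.seed)
    L = len(genome.seq)
    doubled = genome.seq + genome.seq if genome.circular else genome.seq
    target = params.depth * L
    mu = math.log(params.mean_len) - params.sigma**2 / 2
    reads = []
    truth: list[TruthRecord] = []
    total = 0
    i = 0
    while total < target:
        rlen = int(rng.lognormal(mu, params.sigma))
        rlen = max(100, min(rlen, L - 1))
        rid = f"{genome.id}_r{i}"
        if rng.random() < params.chimera_rate:
            seq, intervals = _chimeric_fragment(genome, doubled, rlen, rng)
            event = "chimera"
        else:
            seq, intervals = _origin_fragment(genome, doubled, rlen, rng)
            event = "normal"
        mutated = _mutate_seq(
            seq, params.sub_rate, params.ins_rate, params.del_rate, rng
        )
        reads.append((rid, mutated, None))
        truth.append(TruthRecord(name=rid, event=event, intervals=intervals))
        total += len(mutated)
        i += 1
    return SimulatedReads(reads=ReadSet(reads=reads), truth=truth)


def _origin_fragment(genome, doubled, rlen, rng):
    L = len(genome.seq)
    if genome.circular:
        start = int(rng.integers(0, L))
    else:
        start = int(rng.integers(0, L - rlen + 1))
    frag = doubled[start : start + rlen]
    strand = "+" if rng.random() < 0.5 else "-"
    end = start + rlen
    if end <= L:
        intervals = [(genome.id, start, end, strand)]
    else:  # wraps across the origin
        intervals = [(genome.id, start, L, strand), (genome.id, 0, end - L, strand)]
        if strand == "-":
            intervals = intervals[::-1]
    seq = frag if strand == "+" else reverse_complement(frag)
    return seq, intervals


def _chimeric_fragment(genome, doubled, rlen, rng):
    half = rlen // 2
    parts = []
    intervals = []
    for plen in (half, rlen - half):
        seq, ivs = _origin_fragment(genome, doubled, max(plen, 50), rng)
        parts.append(seq)
        intervals.extend(ivs)
    return "".join(parts), intervals


def simulate_short_reads(
    genome: ContigRecord,
    depth: float,
    read_len: int = 150,
    sub_rate: float = 0.0,
    seed: int = 0,
    insert_mean: float = 350.0,
    insert_sd: float = 50.0,
) -> SimulatedReads:
    """Simulate paired short reads (normal insert sizes, uniform placement)."""
    if read_len > len(genome.seq):
        raise ValueError("read_len exceeds genome length")
    rng = np.random.default_rng(seed)
    L = len(genome.seq)
    target = depth * L
    reads = []
    truth = []
    total = 0
    i = 0
    while total < target:
        insert = int(rng.normal(insert_mean, insert_sd))
        insert = max(read_len, min(insert, L))
        start = int(rng.integers(0, L - insert + 1))
        frag = genome.seq[start : start + insert]
        r1 = frag[:read_len]
        r2 = reverse_complement(frag[-read_len:])
        base = f"{genome.id}_p{i}"
        for suffix, seq, s, e, strand in (
            ("_1", r1, start, start + read_len, "+"),
            ("_2", r2, start + insert - read_len, start + insert, "-"),
        ):
            mutated = _mutate_seq(seq, sub_rate, 0.0, 0.0, rng)
            reads.append((base + suffix, mutated, None))
            truth.append(
                TruthRecord(
                    name=base + suffix,
                    event="normal",
                    intervals=[(genome.id, s, e, strand)],
                )
            )
            total += len(mutated)
        i += 1
    return SimulatedReads(reads=ReadSet(reads=reads), truth=truth)


def plant_chimera(
    a: ContigRecord, b: ContigRecord, pos_a: int, pos_b: int
) -> tuple[ContigRecord, TruthRecord]:
    """Join a[0:pos_a] + b[pos_b:] into one misassembled contig."""
    if not (0 < pos_a < len(a.seq)):
        raise ValueError("pos_a must be strictly inside contig a")
    if not (0 <= pos_b < len(b.seq)):
        raise ValueError("pos_b must leave a non-empty suffix of contig b")
    seq = a.seq[:pos_a] + b.seq[pos_b:]
    contig = ContigRecord(
        id=f"{a.id}|{b.id}_chimera",
        seq=seq,
        circular=False,
        provenance=f"chimera of {a.id}[0:{pos_a}] + {b.id}[{pos_b}:]",
    )
    truth = TruthRecord(
        name=contig.id,
        event="planted_break",
        intervals=[
            (a.id, 0, pos_a, "+"),
            (b.id, pos_b, len(b.seq), "+"),
        ],
    )
    return contig, truth


def plant_terminal_redundancy(
    genome: ContigRecord,
    overlap_bp: int,
    mismatch_rate: float = 0.0,
    seed: int = 0,
) -> tuple[ContigRecord, TruthRecord]:
    """Append a (possibly mutated) copy of the genome's prefix to its end,
    emulating an over-circularized contig."""
    if not (0 < overlap_bp < len(genome.seq)):
        raise ValueError("overlap_bp must be in (0, genome length)")
    rng = np.random.default_rng(seed)
    extra = _mutate_seq(genome.seq[:overlap_bp], mismatch_rate, 0.0, 0.0, rng)
    contig = ContigRecord(
        id=genome.id + "_overcirc",
        seq=genome.seq + extra,
        circular=False,
        provenance=f"over-circularized by {overlap_bp} bp",
    )
    L = len(genome.seq)
    truth = TruthRecord(
        name=contig.id,
        event="terminal_redundancy",
        intervals=[
            (contig.id, 0, overlap_bp, "+"),
            (contig.id, L, L + overlap_bp, "+"),
        ],
    )
    return contig, truth


def mutate_assembly(
    genome: ContigRecord,
    n_subs: int,
    n_ins: int,
    n_del: int,
    seed: int = 0,
) -> tuple[ContigRecord, list[ConsensusEdit]]:
    """Plant substitutions and 1-bp indels; return the mutated draft and the
    truth edits (in mutated-draft coordinates) that restore the original."""
    L = len(genome.seq)
    n_total = n_subs + n_ins + n_del
    if n_total > L // 100:
        raise ValueError("too many mutations for genome length")
    rng = np.random.default_rng(seed)
    positions: set[int] = set()
    for _ in range(1000):
        needed = n_total - len(positions)
        if needed <= 0:
            break
        cand = rng.integers(2, L - 2, size=needed * 2)
        for p in cand:
            p = int(p)
            if all(abs(p - q) >= 3 for q in positions):
                positions.add(p)
            if len(positions) == n_total:
                break
    else:
        raise ValueError("could not place non-colliding mutation sites")
    sites = sorted(positions)
    perm = rng.permutation(n_total)
    kinds = np.array(["sub"] * n_subs + ["ins"] * n_ins + ["del"] * n_del)[perm]

    pieces = []
    edits: list[ConsensusEdit] = []
    prev = 0
    shift = 0  # mutated minus original coordinate
    mid = genome.id + "_draft"
    for p, kind in zip(sites, kinds):
        pieces.append(genome.seq[prev:p])
        orig = genome.seq[p]
        if kind == "sub":
            alt = rng.choice([b for b in "ACGT" if b != orig])
            pieces.append(alt)
            edits.append(ConsensusEdit(mid, p + shift, alt, orig, 0, 0))
            prev = p + 1
        elif kind == "ins":
            ins = str(rng.choice(list("ACGT")))
            pieces.append(ins + orig)
            # correction: delete the inserted base at mutated position p+shift
            edits.append(ConsensusEdit(mid, p + shift, ins, "", 0, 0))
            shift += 1
            prev = p + 1
        else:  # del: drop the original base
            # correction: insert the original base back before mutated pos
            edits.append(ConsensusEdit(mid, p + shift, "", orig, 0, 0))
            shift -= 1
            prev = p + 1
    pieces.append(genome.seq[prev:])
    mutated = ContigRecord(
        id=mid,
        seq="".join(pieces),
        circular=genome.circular,
        provenance=f"mutated: {n_subs} subs, {n_ins} ins, {n_del} del, seed {seed}",
    )
    return mutated, edits
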