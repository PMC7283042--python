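"""Domain types, coordinate conventions and readers/writers.

All internal coordinates are 0-based, half-open. Conversion to and from
1-based conventions happens only at format boundaries (SAM is 1-based in
text form; pysam already normalizes to 0-based, PAF is 0-based natively).
Circularity of a contig is persisted as a ``circular=true`` tag in its
FASTA header and mirrored in report tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ContigRecord",
    "ReadAlignment",
    "GenomicInterval",
    "ReadSet",
    "FormatError",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_alignments",
]

_VALID_BASES = frozenset("ACGTN")
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")

# CIGAR operations that consume the reference / the query
_REF_OPS = frozenset("MDN=X")
_QUERY_OPS = frozenset("MIS=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class FormatError(ValueError):
    """A file or record violates the expected format."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


@dataclass
class ContigRecord:
    """A named DNA sequence with circularity status and provenance."""

    id: str
    seq: str
    circular: bool = False
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("contig id must be non-empty")
        if len(self.seq) < 1:
            raise FormatError(f"contig {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"contig {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomicInterval:
    """A half-open interval [start, end) on a named contig."""

    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on "
                f"{self.contig_id!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class ReadAlignment:
    """One read-to-reference alignment, 0-based half-open on the reference.

    ``left_clip`` / ``right_clip`` are the clipped read bases on either side
    of the aligned segment, in the read's aligned (stored) orientation, so
    the full read length is ``query_aligned_length + left_clip + right_clip``.
    """

    read_id: str
    contig_id: str
    ref_start: int
    ref_end: int
    strand: str
    mapq: int = 60
    is_primary: bool = True
    cigar: str = ""
    left_clip: int = 0
    right_clip: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.ref_start < self.ref_end):
            raise ValueError(
                f"invalid reference interval [{self.ref_start}, {self.ref_end})"
            )
        if self.left_clip < 0 or self.right_clip < 0:
            raise ValueError("clips must be non-negative")
        if self.cigar and self.left_clip == 0 and self.right_clip == 0:
            ops = parse_cigar(self.cigar)
            if ops and ops[0][1] in "SH":
                self.left_clip = ops[0][0]
            if len(ops) > 1 and ops[-1][1] in "SH":
                self.right_clip = ops[-1][0]

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def query_aligned_length(self) -> int:
        """Read bases consumed by the aligned (non-clip) cigar portion."""
        if not self.cigar:
            return self.ref_span
        n = 0
        for length, op in parse_cigar(self.cigar):
            if op in "MI=X":
                n += length
        return n

    @property
    def read_length(self) -> int:
        return self.query_aligned_length + self.left_clip + self.right_clip

    def read_interval(self) -> tuple[int, int]:
        """Half-open interval of the read (aligned orientation) that aligns."""
        return self.left_clip, self.left_clip + self.query_aligned_length


@dataclass
class ReadSet:
    """A collection of (read_id, sequence, optional quality) records."""

    reads: list[tuple[str, str, Optional[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rid, seq, qual in self.reads:
            if rid in seen:
                raise FormatError(f"duplicate read id {rid!r}")
            seen.add(rid)
            if len(seq) < 1:
                raise FormatError(f"read {rid!r}: empty sequence")
            if qual is not None and len(qual) != len(seq):
                raise FormatError(f"read {rid!r}: quality length mismatch")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def sequences(self) -> dict[str, str]:
        return {rid: seq for rid, seq, _ in self.reads}

    def lengths(self) -> list[int]:
        return [len(seq) for _, seq, _ in self.reads]


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) tuples."""
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise FormatError(f"malformed cigar {cigar!r}")
    return ops


def cigar_ref_length(cigar: str) -> int:
    """Reference bases consumed by a CIGAR string."""
    return sum(n for n, op in parse_cigar(cigar) if op in _REF_OPS)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

_CIRC_TAG_RE = re.compile(r"\bcircular=(true|false)\b", re.IGNORECASE)


def read_fasta(path) -> list[ContigRecord]:
    """Read an assembly FASTA into ContigRecords.

    A header tag ``circular=true`` anywhere in the description marks the
    contig circular; ids must be unique.
    """
    path = Path(path)
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        m = _CIRC_TAG_RE.search(rec.description)
        circular = bool(m and m.group(1).lower() == "true")
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: contig {rec.id!r} has empty sequence")
        records.append(ContigRecord(id=rec.id, seq=seq, circular=circular))
    return records


def write_fasta(contigs: Sequence[ContigRecord], path, line_width: int = 60) -> None:
    """Write contigs to FASTA, tagging circular ones in the header."""
    path = Path(path)
    with open(path, "w") as fh:
        for c in contigs:
            desc = []
            if c.circular:
                desc.append("circular=true")
            if c.provenance:
                desc.append(c.provenance)
            header = c.id + ((" " + " ".join(desc)) if desc else "")
            fh.write(f">{header}\n")
            for i in range(0, len(c.seq), line_width):
                fh.write(c.seq[i : i + line_width] + "\n")


def read_fastq(path) -> ReadSet:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        reads.append((rec.id, str(rec.seq).upper(), qual))
    return ReadSet(reads=reads)


def write_fastq(readset: ReadSet, path) -> None:
    records = []
    for rid, seq, qual in readset:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        if qual is None:
            qual = "I" * len(seq)
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# Alignments (SAM/BAM via pysam, PAF parsed directly)
# ---------------------------------------------------------------------------


def read_alignments(
    path,
    format: Optional[str] = None,
    assembly: Optional[Sequence[ContigRecord]] = None,
) -> list[ReadAlignment]:
    """Read alignments from SAM/BAM or PAF into normalized ReadAlignments.

    Unmapped records are skipped. Coordinates are normalized to 0-based
    half-open whatever the source dialect. When *assembly* is given, records
    referencing contigs absent from it raise an error listing the missing ids.
    """
    path = Path(path)
    if format is None:
        format = "paf" if path.suffix.lower() == ".paf" else "sam"
    if format in ("sam", "bam", "sam-bam"):
        alns = _read_sam(path)
    elif format == "paf":
        alns = _read_paf(path)
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    if assembly is not None:
        known = {c.id for c in assembly}
        missing = sorted({a.contig_id for a in alns} - known)
        if missing:
            raise FormatError(
                f"{path}: alignments reference contigs absent from the "
                f"assembly: {missing}"
            )
    return alns


def _read_sam(path: Path) -> list[ReadAlignment]:
    alns: list[ReadAlignment] = []
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            cig = rec.cigartuples or []
            left = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
            right = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
            alns.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    contig_id=rec.reference_name,
                    ref_start=rec.reference_start,
                    ref_end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    mapq=rec.mapping_quality,
                    is_primary=not (rec.is_secondary or rec.is_supplementary),
                    cigar=rec.cigarstring or "",
                    left_clip=left,
                    right_clip=right,
                )
            )
    return alns


def _read_paf(path: Path) -> list[ReadAlignment]:
    alns: list[ReadAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: PAF needs >= 12 columns")
            (qname, qlen, qstart, qend, strand, tname,
             _tlen, tstart, tend, _match, _alen, mapq) = fields[:12]
            if tname == "*":
                continue
            qlen, qstart, qend = int(qlen), int(qstart), int(qend)
            # clips in the aligned orientation: for '-' the read is stored
            # forward in PAF, so the clip preceding ref_start is the one at
            # the read's 3' end
            if strand == "+":
                left, right = qstart, qlen - qend
            else:
                left, right = qlen - qend, qstart
            is_primary = True
            for tag in fields[12:]:
                if tag.startswith("tp:A:"):
                    is_primary = tag[5:] == "P"
            alns.append(
                ReadAlignment(
                    read_id=qname,
                    contig_id=tname,
                    ref_start=int(tstart),
                    ref_end=int(tend),
                    strand=strand,
                    mapq=int(mapq),
                    is_primary=is_primary,
                    cigar="",
                    left_clip=left,
                    right_clip=right,
                )
            )
    return alns
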