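"""Assembly/read statistics and genome-draft quality tiering.

Draft tiers follow the community single-copy-marker conventions: a
high-quality draft needs >90% completeness, <5% contamination, at least one
each of the 5S/16S/23S rRNA loci and at least 18 tRNA loci (strict
inequalities on the percentage thresholds); an intermediate tier relaxes
the completeness floor to 75%; everything else is partial. Completeness and
contamination are inputs, estimated upstream by a single-copy-gene tool —
they are not computed here. Bin contiguity is per-bin N50 divided by total
bin length, which approaches 1 as a bin collapses into a single contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .core import ReadSet

__all__ = [
    "BinQC",
    "compute_n50",
    "bin_contiguity",
    "classify_tier",
    "correct_abundance",
    "shannon_diversity",
    "read_length_stats",
    "read_bin_qc",
    "write_bin_report",
]

TIER_HIGH = "high_quality"
TIER_MEDIUM = "medium_quality"
TIER_PARTIAL = "partial"


@dataclass
class BinQC:
    """QC statistics for one genome bin plus its derived tier."""

    bin_id: str
    contig_ids: list[str] = field(default_factory=list)
    total_len: int = 0
    n50: int = 0
    completeness: float = 0.0
    contamination: float = 0.0
    rrna_5s: int = 0
    rrna_16s: int = 0
    rrna_23s: int = 0
    trna: int = 0
    tier: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("completeness", "contamination"):
            v = getattr(self, name)
            if v is None or not (0 <= v <= 100):
                raise ValueError(f"{name} must be a percentage in [0, 100]")
        if self.n50 > self.total_len:
            raise ValueError("n50 cannot exceed total bin length")
        if self.tier is None:
            self.tier = classify_tier(self)


def compute_n50(lengths: Sequence[int]) -> int:
    """Standard N50: the largest member length L such that sequences of
    length >= L hold at least half the total bases (equivalently, the
    length at which the descending cumulative sum crosses half)."""
    if not len(lengths):
        raise ValueError("cannot compute N50 of an empty length set")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if (arr <= 0).any():
        raise ValueError("all lengths must be positive")
    half = arr.sum() / 2
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[min(idx, len(arr) - 1)])


def bin_contiguity(bin: BinQC) -> float:
    """Per-bin N50 divided by per-bin length; 1.0 for a single-contig bin."""
    if bin.total_len <= 0:
        raise ValueError("bin total length must be positive")
    return bin.n50 / bin.total_len


def classify_tier(bin: BinQC) -> str:
    """Three-level draft tier from completeness/contamination/rRNA/tRNA.

    high_quality: completeness > 90, contamination < 5, each rRNA >= 1,
    tRNA >= 18 (strict inequalities on the percentages). medium_quality:
    same with the completeness floor relaxed to > 75. Else partial.
    """
    for name in ("completeness", "contamination", "rrna_5s", "rrna_16s",
                 "rrna_23s", "trna"):
        if getattr(bin, name) is None:
            raise ValueError(f"missing QC field {name!r} for bin {bin.bin_id}")
    loci_ok = (
        bin.rrna_5s >= 1 and bin.rrna_16s >= 1 and bin.rrna_23s >= 1
        and bin.trna >= 18
    )
    if loci_ok and bin.contamination < 5:
        if bin.completeness > 90:
            return TIER_HIGH
        if bin.completeness > 75:
            return TIER_MEDIUM
    return TIER_PARTIAL


def correct_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Correct observed read-count composition for relative genome size.

    Input columns: ``taxon_id``, ``read_count``, ``genome_len``. Each
    taxon's per-base rate count/len is renormalized to sum to 1 and returned
    in a ``corrected_fraction`` column. Larger genomes attract
    proportionally more reads at equal cell abundance, so dividing by
    genome length recovers the organismal composition.
    """
    out = table.copy()
    if (out["genome_len"] <= 0).any():
        raise ValueError("genome_len must be positive for all taxa")
    rate = out["read_count"] / out["genome_len"]
    out["corrected_fraction"] = rate / rate.sum()
    return out


def shannon_diversity(fractions: Sequence[float]) -> float:
    """Shannon index H = -sum p_i ln p_i in nats; zero fractions skipped."""
    p = np.asarray(fractions, dtype=float)
    if (p < 0).any():
        raise ValueError("fractions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1 (got {p.sum()!r})")
    return float(entropy(p))


def read_length_stats(reads: ReadSet, bin_width: int = 1000) -> dict:
    """Read-set summary: count, total bases, mean, N50 and a histogram."""
    lengths = np.asarray(reads.lengths(), dtype=np.int64)
    if not len(lengths):
        raise ValueError("empty read set")
    hi = int(lengths.max()) + bin_width
    edges = np.arange(0, hi + bin_width, bin_width)
    hist, _ = np.histogram(lengths, bins=edges)
    return {
        "n_reads": int(len(lengths)),
        "total_bp": int(lengths.sum()),
        "mean": float(lengths.mean()),
        "n50": compute_n50(lengths),
        "histogram": [
            (int(s), int(e), int(c)) for s, e, c in zip(edges, edges[1:], hist)
        ],
    }


def read_bin_qc(path) -> list[BinQC]:
    """Load a bin-QC TSV (bin_id, contig_ids, total_len, n50, completeness,
    contamination, rrna_5s, rrna_16s, rrna_23s, trna)."""
    df = pd.read_csv(path, sep="\t")
    bins = []
    for row in df.itertuples(index=False):
        contigs = str(row.contig_ids).split(",") if hasattr(row, "contig_ids") else []
        bins.append(
            BinQC(
                bin_id=str(row.bin_id),
                contig_ids=[c for c in contigs if c],
                total_len=int(row.total_len),
                n50=int(row.n50),
                completeness=float(row.completeness),
                contamination=float(row.contamination),
                rrna_5s=int(row.rrna_5s),
                rrna_16s=int(row.rrna_16s),
                rrna_23s=int(row.rrna_23s),
                trna=int(row.trna),
            )
        )
    return bins


def write_bin_report(bins: Sequence[BinQC], path) -> pd.DataFrame:
    """Write a per-bin report (size in Mbp, N50, contiguity, tier) as TSV."""
    df = pd.DataFrame(
        [
            {
                "bin_id": b.bin_id,
                "size_mbp": round(b.total_len / 1e6, 3),
                "n50": b.n50,
                "contiguity": round(bin_contiguity(b), 4),
                "completeness": b.completeness,
                "contamination": b.contamination,
                "tier": b.tier,
            }
            for b in bins
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
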