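"""Draft QC: N50, bin contiguity, quality tiers, genome-size-corrected
abundance and Shannon diversity."""

import pandas as pd

from lathework import (
    BinQC, bin_contiguity, classify_tier, compute_n50, correct_abundance,
    shannon_diversity,
)

lengths = [3_200_000, 450_000, 120_000, 80_000]
print(f"assembly N50 of {lengths}: {compute_n50(lengths):,} bp")

b = BinQC(bin_id="bin1", total_len=sum(lengths), n50=compute_n50(lengths),
          completeness=96.5, contamination=1.2,
          rrna_5s=1, rrna_16s=2, rrna_23s=1, trna=45)
print(f"bin contiguity {bin_contiguity(b):.3f} "
      f"(1.0 would mean a single-contig bin); tier: {classify_tier(b)}")

# equal read counts do not mean equal organism abundance: a genome twice as
# long attracts twice the reads per cell, so divide by genome length
table = pd.DataFrame({
    "taxon_id": ["A", "B", "C"],
    "read_count": [6_000, 6_000, 3_000],
    "genome_len": [6e6, 3e6, 3e6],
})
out = correct_abundance(table)
print(out[["taxon_id", "corrected_fraction"]].to_string(index=False))
h = shannon_diversity(out["corrected_fraction"].tolist())
print(f"Shannon diversity: {h:.4f} nats")
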