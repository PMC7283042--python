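"""Circularize contigs: trim terminal redundancy, confirm closure with reads.

An assembler walking past the wrap-around point of a circular chromosome
emits the same sequence at both contig ends; self-alignment finds and trims
the redundant copy. Independently, reads crossing the wrap-around align in
two pieces (end of the contig + start of the contig), and enough agreeing
split reads confirm the genome is closed.
"""

from lathework import (
    ContigRecord, GenomeSpec, ReadSimParams, detect_terminal_redundancy,
    make_genome, map_reads_anchored, plant_terminal_redundancy,
    simulate_long_reads, trim_overcircularized,
)
from lathework.circularize import test_spanning_closure

genome, _ = make_genome(GenomeSpec(length=40_000, circular=True, seed=7))

# --- method 1: terminal redundancy
over, _ = plant_terminal_redundancy(genome, overlap_bp=2_000)
overlap = detect_terminal_redundancy(over)
print(f"over-circularized contig: {len(over.seq)} bp")
print(f"terminal redundancy: {overlap.overlap_len} bp at identity "
      f"{overlap.identity:.3f}")
trimmed = trim_overcircularized(over, overlap)
print(f"trimmed to {len(trimmed.seq)} bp (true genome length: "
      f"{len(genome.seq)} bp), circular={trimmed.circular}")

# --- method 2: spanning closure
linear = ContigRecord(id=genome.id, seq=genome.seq)  # no redundancy present
sim = simulate_long_reads(genome, ReadSimParams(depth=30, seed=8))
alignments = map_reads_anchored(sim.reads, [linear])
result = test_spanning_closure(linear, alignments)
print(f"closure test: status={result.status}, junction at "
      f"{result.junction_pos}, supported by {result.n_support_reads} "
      f"split reads")
# junction 0 means the contig already starts exactly at the wrap-around
# point; each supporting read aligned in tail+head pieces around it.
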