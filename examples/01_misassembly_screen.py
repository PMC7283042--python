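"""Detect a planted misassembly by spanning-read coverage.

Builds a chimeric contig from halves of two unrelated 60-kb genomes,
simulates 30x error-free long reads from each true genome, maps them to the
chimera and screens for windows no read spans. The junction shows up as a
spanning-coverage hole and the contig is broken there.
"""

from lathework import (
    GenomeSpec, ReadSimParams, make_genome, map_reads_anchored,
    plant_chimera, screen_assembly, simulate_long_reads,
)

a, _ = make_genome(GenomeSpec(length=60_000, seed=1))
b, _ = make_genome(GenomeSpec(length=60_000, seed=2))
chimera, truth = plant_chimera(a, b, pos_a=30_000, pos_b=30_000)
print(f"chimeric contig: {len(chimera.seq)} bp, true junction at 30,000")

alignments = []
for genome, seed in ((a, 3), (b, 4)):
    sim = simulate_long_reads(genome, ReadSimParams(depth=30, seed=seed))
    alignments += map_reads_anchored(sim.reads, [chimera])
print(f"mapped {len(alignments)} alignments from the two true genomes")

broken, windows, breaks = screen_assembly([chimera], alignments,
                                          window_factor=0.25)
wsize = len(windows[0].interval)
for site in breaks:
    print(f"break called at {site.position:,} "
          f"(window size {wsize}, {site.spanning_count} spanning reads)")
print(f"fragments: {[f'{f.id}:{len(f.seq)}bp' for f in broken]}")
# The break position is within one window of the planted junction: windows
# inside either true genome are spanned by dozens of reads, while no read
# can span the foreign junction, so coverage drops to ~0 exactly there.
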