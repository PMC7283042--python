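# lathework

Finishing toolkit for long-read metagenome assemblies: misassembly
screening by spanning-read coverage, contig circularization,
segment-parallel short-read polishing, and genome-draft QC — plus a
synthetic-data generator that makes every stage verifiable end to end
without any external data or aligner.

## Who it is for

Long reads (nanopore in particular) can assemble single-contig bacterial
genomes directly from complex communities such as human stool, but the raw
assemblies need finishing before they are usable as reference genomes:
chimeric joins must be found and broken, contigs representing closed
circular chromosomes must be recognized and trimmed to exactly one genome
copy, and the error-rich consensus must be polished with accurate short
reads. `lathework` implements these bespoke finishing stages as a tested
Python library with a thin `lathework` CLI. External heavyweight steps
(assemblers, mergers, long-read polishers) are delegation points, not
re-implementations.

## The methods

**Misassembly screen.** A misassembled junction cannot be crossed by reads
from the true genomes: read alignments are soft-clipped at the breakpoint.
Each contig is tiled into windows of size *w* = 0.75 × mean read length
(clamped to [500 bp, 20 kb]; configurable), spanning coverage is counted
per window — an alignment spans a window iff its aligned reference
interval contains it — and windows spanned by ≤ 1 read are flagged.
Two phase-shifted tilings (offsets 0 and *w*/2) ensure every position is
interior to some window; windows within a mean read length of the contig
ends are exempt, since reads cannot overhang a linear contig. Contigs are
broken at the midpoint of each flagged region.

**Circularization.** Two complementary tests locate the wrap-around
(junction) point of a closed genome: (1) self-alignment of the contig's
prefix against its suffix detects the redundant copy left by assembling
past the wrap-around, which is trimmed (head copy retained); (2) reads
crossing the junction align in two pieces — one reaching the contig end,
one starting at the contig start, tail before head on the read — and
≥ 2 such reads agreeing on a junction (median, IQR ≤ 100 bp) call the
contig circular. An externally assembled spanning contig can substitute
for the read evidence.

**Polishing.** The assembly is partitioned into 100-kb segments; reads
overlapping each segment are deterministically downsampled to 50×; a
base-level pileup calls substitutions, insertions and deletions by a
plurality rule (depth ≥ 5, alternate fraction ≥ 0.7, ties to the
reference); per-segment edit lists are aggregated (deduplicated across
boundaries, conflicts resolved by read support) and applied in one pass —
so the result is independent of how segments were distributed over
workers. Edits in or adjacent to homopolymer runs (≥ 4 bp) are flagged.
Edits are exchanged as VCF.

**QC metrics.** N50; bin contiguity = bin N50 / bin length (→ 1 as a bin
approaches a single contig); draft tiers from completeness (>90 high,
>75 medium), contamination (<5), rRNA (≥1 each of 5S/16S/23S) and tRNA
(≥18) counts; read-count abundance corrected for relative genome size
(count/length, renormalized); Shannon diversity H = −Σ pᵢ ln pᵢ.

## Worked example

```pycon
>>> from lathework import (GenomeSpec, ReadSimParams, make_genome,
...     map_reads_anchored, plant_chimera, screen_assembly,
...     simulate_long_reads)
>>> a, _ = make_genome(GenomeSpec(length=60_000, seed=1))
>>> b, _ = make_genome(GenomeSpec(length=60_000, seed=2))
>>> chimera, _ = plant_chimera(a, b, pos_a=30_000, pos_b=30_000)
>>> alns = []
>>> for genome, seed in ((a, 3), (b, 4)):
...     sim = simulate_long_reads(genome, ReadSimParams(depth=30, seed=seed))
...     alns += map_reads_anchored(sim.reads, [chimera])
>>> broken, windows, breaks = screen_assembly([chimera], alns,
...                                           window_factor=0.25)
>>> [(s.position, s.spanning_count) for s in breaks]
[(30115, 0)]
>>> [len(f.seq) for f in broken]
[30115, 29885]
```

The chimeric join of two unrelated genomes at 30,000 bp is recovered at
30,115 — within one window (1,268 bp) of the truth — because no read spans
the foreign junction (`spanning_count` 0) while every window inside either
true genome is spanned by dozens of reads. The `examples/` directory holds
one short narrative script per capability (screen, circularize, polish, QC
metrics, full pipeline); each prints the numbers it computes and what they
mean. The same stages are available from the shell:

```bash
lathework simulate genome --length 60000 --seed 1 --out g.fasta
lathework misassembly --assembly asm.fasta --reads long.fastq --outdir out/
lathework run --config pipeline.yaml --seed 5
```

## Scope

The internal k-mer-anchored mapper exists to make the package
self-testable on synthetic, low-error reads; real nanopore data should
arrive pre-aligned (SAM/BAM/PAF). Assembly, merging, long-read polishing
(Racon/Medaka-class tools) and completeness/contamination estimation are
out of scope and enter only as inputs or delegated commands. See
`docs/methods.md` for models, parameter defaults and limitations.
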