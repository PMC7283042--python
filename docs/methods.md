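# Methods

This note documents the models and procedures implemented in `lathework`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Coordinates and conventions

All internal coordinates are 0-based, half-open; conversion happens only at
format boundaries (SAM text is 1-based; pysam already normalizes; PAF and
BED are 0-based). Clip lengths on alignments are expressed in the read's
aligned (stored) orientation, as in SAM — for a reverse-strand read the
"left" clip precedes the alignment on the forward reference. Circularity is
persisted as a `circular=true` FASTA header tag and mirrored in report
TSVs. `N` bases are legal in sequences but never counted as matches or
pileup evidence.

## Misassembly screen

Model: a chimeric join between loci that are not adjacent in any template
molecule cannot be crossed by a read; alignments are clipped at the
breakpoint. Absence of spanning reads over a window therefore flags the
window as containing a candidate misassembly, while one spanning read is
still compatible with a single chimeric read.

- *Window size*: `w = clamp(round(factor × mean read length), 500 bp,
  20 kb)`, `factor` default 0.75. The screen's false-positive guarantee
  improves as windows shrink relative to reads (spanning-read count per
  window grows roughly as `depth × (1 − w/mean)`); the fixtures in the
  acceptance harness use `factor = 0.25` (mean read length ≥ 4 windows),
  where 30× coverage yields ~20 expected spanning reads per window and the
  probability of a chance unspanned window is negligible.
- *Spanning rule*: an alignment spans a window iff its aligned reference
  interval contains the window (boundaries inclusive); clips are ignored,
  because clipping at breakpoints is exactly the signal. Primary alignments
  with mapq ≥ 10 count by default.
- *Dual-phase tiling*: the screen tiles each contig twice, at grid offsets
  0 and w/2, and merges flagged windows from both phases. With a single
  grid, a breakpoint lying exactly on a window boundary is contained by no
  window — alignments clipped at the breakpoint still span both adjacent
  windows — and is invisible; the second phase guarantees every position is
  strictly interior to at least one window it is evaluated in.
- *Edge exemption*: windows within `max(w, mean read length)` of a contig
  end are exempt. Reads cannot overhang a linear contig, so spanning
  coverage decays to zero over roughly one read length at each terminus;
  exempting only one window length left a band of coverage-starved windows
  that occasionally produced false breaks at 30×.
- *Breaking*: adjacent/overlapping flagged windows merge into one region;
  the contig is cut at the region midpoint (no bases deleted — conservation
  over precision, since the junction is only localized to a window
  anyway). Fragments below 1 kb are dropped and logged; fragments of a
  broken contig lose any circular flag.

## Circularization

Two tests, run per contig (results are independent of contig order):

1. **Terminal redundancy.** If an assembler walks past the wrap-around
   point, the contig is `S + S[0:v]` for genome `S` and overlap `v`.
   Shared k-mers (k = 17) between the first and last `max_search_bp`
   (default 50 kb) propose candidate overlap lengths (one per diagonal);
   each candidate prefix/suffix pair is verified by global (NW) edlib
   alignment; the longest candidate with `overlap ≥ 1 kb` and
   `identity ≥ 0.95` wins. The suffix copy is cut and the prefix retained:
   where the copies disagree, polishing later re-corrects the retained
   copy. A regression guard re-runs detection on trimmed output to exclude
   off-by-one residues.
2. **Spanning closure.** A read crossing the junction of a circular genome
   linearized at position j aligns in two pieces: one ending at the contig
   end, one starting at the contig start, tail before head in stored
   orientation. Support requires both pieces on the same strand, each
   reaching within `end_window_bp` (default 1 kb) of its terminus. With
   ≥ `min_support` (default 2) supporting reads whose implied junctions
   agree (circular median; inter-quartile spread ≤ `junction_tol_bp`,
   default 100 bp), the contig is circular; zero support → linear;
   anything else (insufficient or conflicting support) → ambiguous. The
   two thresholds are deliberately separate: the terminus window expresses
   mapping slack, the tolerance expresses junction agreement. An
   externally assembled spanning contig may be supplied as the evidence
   instead (customarily with `min_support = 1`).

Rotation of a confirmed-circular contig to a user-chosen origin is content
preserving (`doubled(original)` contains the rotated sequence); no
biological origin is inferred.

## Segment-parallel polishing

The unit of work is a ~100-kb segment (trailing remainders under half a
segment merge into the previous one; short contigs form one segment).
Per segment:

- *Downsampling* to 50× target depth keeps each overlapping alignment with
  probability `min(1, target/observed mean depth)`, decided by a stable
  blake2b hash of (seed, segment index, read id) — deterministic,
  order-independent, and unbiased (retained depth within 10% of target
  whenever observed ≥ 2× target).
- *Pileup* by cigar walk over the aligned reads (array-backed counts of
  A/C/G/T/deletion per column; insertions keyed by the position they
  follow; bases under `min_base_q` excluded when qualities are present).
- *Edit calling* by plurality: at depth ≥ 5, call the plurality
  non-reference base (or deletion, or one inserted sequence) when its
  fraction of the column depth is ≥ 0.7 and strictly exceeds the reference
  support; ties break toward the reference. These defaults trade recall
  for a near-zero false-edit rate on clean data (error-free reads over an
  error-free assembly produce zero edits at any depth).

Aggregation concatenates per-segment lists, deduplicates identical edits
reported by adjoining segments (keeping max support), and resolves
overlapping conflicts in favor of higher read support (ties: the
lower-position edit). Application proceeds per contig from highest to
lowest coordinate so earlier positions stay valid; the output length
equals input length plus the signed sum of edit deltas, and the applied
reference allele is checked against the sequence. Because aggregation is
order-insensitive and application is single-pass, results are invariant to
segment processing order and to segment size — the property that makes the
segment-parallel scheme sound. Edits whose reference context contains a
single-base run ≥ 4 bp overlapping or within 1 bp of the edit are flagged
as homopolymer-associated. VCF import/export uses the anchored-base indel
convention (left-anchored; right-anchored only at position 0).

For comparing edit sets (e.g. calls vs planted truth), `left_align_edit`
canonicalizes 1-bp indels to their leftmost equivalent placement within a
repeat run — deleting any base of a homopolymer is the same correction.

## Internal read mapper

`map_reads_anchored` exists so the package is self-testable without an
external aligner; it targets synthetic, low-error reads, and real data
should arrive pre-aligned. Exact k-mers (k = 17) sampled along the read
(adaptive stride, dense retry if nothing hits) vote for (contig, strand,
diagonal) clusters. The best cluster is first tried as a full-length
edlib (HW-mode) alignment; the alignment path is then trimmed to its
maximum-scoring contiguous stretch (Kadane over match/mismatch/gap blocks,
+2/−4), which converts foreign terminal sequence — e.g. the far side of a
chimeric junction — into soft clips the way a production aligner would.
If less than 90% of the read survives trimming, the read is instead mapped
per cluster (X-drop extension from the anchored block, then global
alignment), yielding split alignments with one-sided clips for chimeric
and wrap-around reads; the largest piece is marked primary. Reads that
anchor nowhere are reported unaligned. Known limitation: split pieces
shorter than ~10% of the read (or than the k-mer sampling stride) may be
dropped, so closure support counts undercount wrap reads whose minor piece
is tiny — harmless for junction estimation, which uses the surviving
pieces.

## Synthetic data

Generators are pure functions of their parameters and seed (bit-identical
reruns) and every fixture carries truth records sufficient to score the
consuming stage.

- Genomes: i.i.d. bases at a target GC (realized GC within ±2% at ≥10 kb),
  with optional exact repeat copies at recorded positions.
- Long reads: lognormal lengths (default mean 5 kb, σ = 0.35 — the scale
  of nanopore metagenome libraries), uniform start positions, wrap-around
  sampling on circular genomes, uniform per-base substitution/indel
  errors, and chimeras formed by joining two independently placed
  fragments. Not emulated: homopolymer-biased error spectra, quality
  strings correlated with error, length-dependent coverage bias.
- Short reads: paired, insert ~ Normal(350, 50) truncated, uniform
  placement, substitution errors only.
- Defective drafts: chimeric joins (`a[:pos_a] + b[pos_b:]` with the truth
  junction), over-circularized contigs (genome + mutated copy of its
  prefix), and mutated drafts whose truth edits, expressed in draft
  coordinates, exactly restore the original (an inverse-property test).

Because errors are uniform and reads error-free in most fixtures, passing
tests demonstrate the correctness of the windowing/closure/aggregation
logic and its coordinate handling — not robustness to real nanopore error
profiles, reference bias, or strain mixtures.

## Problem sizes and determinism

Default fixture scales: 100-kb genomes at 30× long reads for the
misassembly screen (50 chimeric + 20 clean replicates in the acceptance
harness), 40–50-kb genomes for circularization (3 trim sizes, 50 closure
replicates, 20 linear controls), a 200-kb draft with 50 substitutions +
20 one-bp indels at 50× short reads for polishing, and a 30-kb circular
fixture for the end-to-end pipeline. The default pytest suite exercises
the same scenarios, generally at one or a few replicates per property;
`scripts/acceptance.py` runs the full replicate counts. All randomness
flows from explicit integer seeds; the pipeline manifest records
parameters and SHA-256 checksums of every output, and reruns with the same
config and seed are byte-identical.

## Known limitations

- The misassembly screen cannot see junctions supported by ≥ 2 chimeric
  reads, and does not type the event (inversion vs translocation).
- Circularization assumes a single-genome contig; plasmid/chromosome
  classification and biologically meaningful rotation origins are out of
  scope.
- The polisher is haploid/single-strain: mixed-strain columns fail the
  0.7-plurality rule and are (correctly, for this model) left unedited.
- Completeness/contamination are inputs from single-copy-gene tools, whose
  own estimates can be inaccurate; the tier rule is only as good as they
  are.
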