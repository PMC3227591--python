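# Methods

## Scope and model

fusionscout detects gene-fusion transcripts in RNA-Seq data at desk scale: a
small reference genome (FASTA), transcript annotation (GTF or BED12), and
single- or paired-end reads (FASTQ, or pre-computed genomic alignments in
SAM/BAM). The method assumes fusion transcripts join complete exons of two
genes at annotated exon boundaries — the common case for translocation-derived
chimeras — and does not model breakpoints inside exons, trans-splicing, or
novel (unannotated) exons.

Coordinates are 0-based half-open internally and 1-based inclusive at the file
interfaces (GTF/SAM convention). One `GeneModel` is built per transcript;
multi-transcript genes contribute one junction library per transcript and
results collapse to gene level by `gene_id`. Minus-strand genes are handled
entirely in transcript orientation (exon lists reversed, sequences
reverse-complemented on access).

## Junction libraries

For read length *x*, a junction record joins `min(x−5, exon length)` bases
from the 3′ end of the upstream exon with `min(x−5, exon length)` bases from
the 5′ start of the downstream exon. Any read of length *x* fully contained in
such a sequence overlaps each side by ≥ 5 bases — the property the spanning-
read search relies on, asserted by exhaustive placement in the tests. The
within-gene library has one record per adjacent exon pair; the fusion library
for a candidate takes the full Cartesian product of 5′-partner × 3′-partner
exons, so alternate fusion isoforms (different donor exons sharing one
acceptor) are detectable, and swapping the arguments yields the disjoint
reciprocal-fusion library.

## Alignment surrogates

The package targets toy-scale fixtures; for real data, import genomic
alignments via SAM/BAM.

* **End-to-end aligner** — pigeonhole k-mer seeding (default k = 12,
  `max_mismatches + 1` disjoint seeds) with Hamming verification. All
  placements within the mismatch budget (default 2) are found whenever the
  read hosts the disjoint seeds; "unique" means exactly one placement at the
  best mismatch count. Reads shorter than k fall back to a brute-force scan.
* **Local aligner** (partial alignments) — Smith–Waterman scoring +1/−1 with
  −2 per gap position, minimum block score 16, both strands; backed by
  `Bio.Align.PairwiseAligner` and checked in the tests against an independent
  hand-written DP on 200 seeded instances.
* **Exact matcher** (short remainders) — exhaustive exact substring search,
  all placements reported, minimum fragment length 8 to bound spurious hits.
* **SAM import** — "unique" = MAPQ ≥ 1 (configurable), "fully mapped" =
  ungapped, unclipped CIGAR, mismatches from the NM tag.

All scoring constants are exposed in `PipelineConfig`; the defaults were fixed
once and are not data-fitted.

## Single-end stage

Group A keeps every qualifying partial alignment of an unmapped read (coverage
20–70 % of the read, block end within 5 bp of an exon boundary), not just the
best one: the correct placement of a junction-spanning read can tie or lose
narrowly against a chance extension across the junction, and the Group B
match disambiguates. "20–70 %" is interpreted as block coverage of the read
with the block itself near-exact (the natural reading for a local aligner);
both bounds are configurable. Reads partially hitting more than 5 genes are
discarded as ambiguous. Group B requires the full remainder to match an exon
exactly within 5 bp of either exon end; remainders matching several genes are
dropped as ambiguous. A GFCR requires the two blocks to partition the read
(gap tolerance 0 by default) in two different genes; GFCRs are oriented to
transcript sense using the Group A alignment strand and tallied per ordered
gene pair, collapsing identical placements (the PCR-duplicate rule). The
"manual review" annotations are non-destructive flags: `repetitive_region`
(remainder placements at ≥ 5 loci) and `same_family` (gene names sharing an
alphabetic root and differing only by a numeric suffix).

## Paired-end stage

Discordant pairs need both mates fully and uniquely mapped, on different
chromosomes or ≥ 1 Mb apart (the distance guard against large introns).
After mRNA realignment, the mate aligned to the mRNA forward strand is the
upstream (5′) partner — a fragment is a contiguous piece of the fusion
transcript, so its forward-aligning mate always sits on the 5′ side regardless
of which mate was sequenced first. Ambiguous orientations are emitted under
both orientations rather than guessed. Reciprocal fusions therefore appear as
two distinct candidates and are never merged.

PEFS = 2P − D − 0.5M. P counts all identified pairs; D penalises duplicates
separately (each supporting read beyond the first at an identical start
coordinate), matching the published worked example's arithmetic. M sums
mismatches over the supporting reads' genomic alignments by default; a config
switch (`mismatch_source`) uses the transcript realignment instead. On toy
genomes, exon territories are small, so coincidental start-coordinate
collisions inflate D beyond the injected PCR duplicates — the same behaviour
the rule has on real data, just more visible; tests therefore recompute the
expected D independently from the simulator's fragment coordinates.

Prioritized candidates (P ≥ 3 and PEFS ≥ 5, sorted by PEFS, then P, then gene
pair) are confirmed by aligning the remaining unmapped reads against the
fusion junction library; only uniquely placed reads with ≥ 5 bp on each side
count. The modal junction is `predicted_junction`; every junction with ≥ 1
read is kept as an isoform. With zero spanning reads the candidate is flagged
`unconfirmed` and the junction falls back to the innermost exons touched by
the flanking mates (exon attribution uses the alignment midpoint so that
placements overhanging an exon edge by a couple of bases within the mismatch
budget land in the right exon).

**In-frame call.** With donor phase = (coding bases of the 5′ partner up to
the junction) mod 3 and acceptor phase = (coding bases of the 3′ partner
before its retained exon) mod 3: equal phases → `Y`, unequal → `N`. A
breakpoint in the 5′ partner's 5′ UTR (or upstream of the 3′ partner's CDS) →
`UTR-truncation`: no fusion protein, but the downstream ORF survives intact
under the 5′ partner's promoter. A breakpoint beyond either CDS end → `N` (no
fusion ORF is possible); a missing CDS → `unknown` with a warning.

## Expression profiling

Per-exon counts take uniquely, fully mapped reads overlapping the exon by
≥ 1 bp; a read straddling two exons counts once for each (the straddle rule is
a package choice; exon assignment of boundary reads is inherently ambiguous).
RPKM = count / (exon kb) / (mapped reads in millions). Fold change uses the
arithmetic mean of the reference samples' RPKM per exon and a pseudocount
(default 0.1 RPKM) so zero-reference exons stay finite; such exons are
flagged. `breakpoint_discordance` reports mean log₂ FC upstream (exons before
the breakpoint) versus downstream (breakpoint exon onward) and their
difference; a breakpoint at the first exon leaves the upstream block empty and
the difference undefined. No significance test is attached — the quantity is
descriptive, as in the underlying method.

## Synthetic data generator

The generator emulates the data regime the detection stages were designed
for, with one seeded NumPy stream per run (identical specs are byte-identical):

* genome: 2 chromosomes × 30 kb of uniform random sequence (defaults);
* genes: 8 non-overlapping genes, 3–6 exons of 80–220 bp (the human mean exon
  is ≈ 150 bp; much shorter exons would make most mates cross splice
  boundaries, a regime unlike the annotation the method targets), introns
  60–300 bp, random strand, CDS start within the first third of the
  transcript so in-frame, out-of-frame and 5′-UTR-breakpoint fusions are all
  constructible;
* fusion transcripts: exons 1..e5 of the 5′ partner + exons e3..last of the
  3′ partner, optional reciprocal event (e3−1 → e5+1), per-event expression
  multiplier implementing 3′-partner overexpression;
* reads: 50 bp SE or PE (defaults), uniform fragment starts, PE fragments
  150 ± 20 bp — chosen once so fragments are small relative to the 300–800 bp
  toy transcripts, as real inserts (~200 bp) are relative to real mRNAs;
  substitution-only errors (i.i.d., default 0), Bernoulli PCR duplicates
  re-emitting fragments at identical coordinates, unstranded mate-1/mate-2
  assignment;
* truth: per-read provenance (source transcript, coordinates, duplicate and
  junction-spanning flags, error count) plus per-event junction sequences and
  frame labels computed by independent phase bookkeeping.

What the generator does **not** emulate — quality-score structure, GC and
positional bias, indels, intronic/pre-mRNA reads, multi-isoform wild-type
genes, and genomic background reads. Passing tests therefore demonstrate the
pipeline's logic under clean assumptions, not its error tolerance on real
libraries; real-data use is expected to go through imported SAM/BAM
alignments from a production aligner.

## Problem sizes and numerical choices

Test fixtures use 5–8 genes on 15–40 kb genomes at 6–20× coverage (hundreds to
~2000 reads), where every stage runs in well under a second; property suites
use 10–20 seeds and 200 alignment instances. PEFS is reported to one decimal
(its increments are halves, so the value is exact). Ties in candidate ranking
break by pair count, then lexicographic gene pair; the modal-junction tie
breaks toward the higher exon ordinals (deterministic). Degenerate inputs are
errors, not silent results: empty target sets, zero mapped reads for RPKM,
trims longer than the read, out-of-range exon ordinals and transcript
positions all raise with the offending record named.

## Known limitations

The toy aligner has no gapped or intron-aware mode, so it cannot place reads
across unannotated junctions; indels in reads defeat the Hamming verification
(real data should come in as SAM). GFCR orientation relies on the local
alignment strand and can mis-orient palindromic blocks. The duplicate rule
cannot distinguish PCR duplicates from coincidental co-starts (inherent to the
definition). Single-exon genes produce no splice junctions and cannot donate
breakpoints beyond their single boundary. No genomic (DNA-level) breakpoint
inference, CNV integration or cohort recurrence screening is attempted.
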