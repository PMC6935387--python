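# Methods

This note documents the models, conventions and design choices behind
`splicechar`, in the order the pipeline applies them.

## Coordinates and annotation

All internal coordinates are 0-based half-open `[start, end)`; conversion
happens only at file boundaries (GTF is 1-based closed; rMATS `*_0base`/
`*ES` starts and `*End`/`*EE` ends are already half-open). Each gene's
**reference transcript** is its longest protein-coding transcript that
carries a parsed transcript support level (TSL 1–5); "longest" means
summed exon (mature) length, not genomic span. Ties break by lowest TSL,
then lexicographically smallest transcript id — explicit choices, since
any rule must be deterministic. Transcripts with TSL "NA" or no TSL
attribute never qualify. Mitochondrial chromosomes default to
`{chrM, MT, chrMT}` and are configurable.

## Event handling

Events with p < 0.05 **and** FDR < 0.05 (both strict) are kept. Direction
is derived from the sign of `IncLevelDifference = IncLevel1 − IncLevel2`
together with the mandatory `g1_is_wildtype` flag; "inclusion" means exon
inclusion for skipped exons and intron inclusion for retained introns, so
a negative difference with wild-type as group 1 means more retention but
*less* skipping in the mutant. A zero difference after the significance
filter is treated as an error rather than silently assigned. A5SS, A3SS
and MXE events are parsed, filtered, direction-classified and counted
(including the multi-event-gene overlap summary) but are not feature
characterized; only retained introns and skipped exons are.

## Control constructs

Internal controls are E-I-E (for retained introns) or E-I-E-I-E (for
skipped exons) windows over consecutive exons/introns of the event gene's
reference transcript. A candidate is valid if its genomic span overlaps
the footprint of **no** filtered event of that gene, of any kind — the
strictest reading, preventing an intron control from sitting inside a
skipped-exon event. One candidate per event is drawn uniformly under the
run's seeded stream; an empty pool is a logged, valid outcome (common for
low-exon-number transcripts). Candidates are enumerated in transcript
(5′→3′) order so that the seeded draw is invariant under mirroring the
genome. External controls take the `external_pool_size` (default 1200,
matching a highly-expressed-gene background; fixtures use 150) most
expressed genes that are non-mitochondrial, absent from all five filtered
event tables, and have a qualifying reference transcript (≥3 exons for
E-I-E-I-E); expression ties break by gene id. One window per gene is
sampled with no footprint exclusion. The expression column is used as
given; its normalization (TPM, expected counts, …) is the caller's
concern, since only the ranking matters.

## Splice-site scoring

Donor windows are 9 nt (last 3 exonic + first 6 intronic), acceptor
windows 23 nt (last 20 intronic + first 3 exonic) — the MaxEntScan window
conventions, so published score tables plug in unchanged via the optional
lookup mode. The default scorer is a first-order positional log-odds
model trained on every unique intron of every reference transcript in the
supplied annotation: `probs[p][b] = (count + κ) / (N + 4κ)` with
pseudocount κ = 0.5, scored as `Σ_p log2(probs[p][b_p] / bg[b_p])` in
bits. Only GT..AG introns train the model; non-canonical introns are
still scored as-is (both counts logged). The background defaults to the
genome's mononucleotide composition with complementary bases pooled
(i.e. the double-stranded composition), which makes every score invariant
under reverse-complementing the assembly; a uniform background is a flag.
This scorer is a calibrated monotone measure of site strength — the
pipeline's claims are group comparisons, which any such scorer supports —
and does not reproduce a maximum-entropy dependency decomposition.

## Branch points

Candidates are every adenosine whose distance to the intron's 3′ end lies
in `[search_min, search_max]` (defaults 15 and 500 nt) and whose 7-mer
context fits in the intron. The context window places the branch A at
position 5 of 7 (five upstream bases, the A, one downstream), scored
against a fixed TACTAAC-style consensus weight matrix shipped with the
package, plus `w ×` the pyrimidine fraction of the 25 nt immediately 3′
of the A (w = 2.0 bits by default, the polypyrimidine-tract term). The
single best-scoring candidate is reported; ties go to the candidate
closest to the 3′ splice site. The reported BPS–3′SS distance is the
number of nucleotides strictly 3′ of the branch A. Introns shorter than
`search_min + 7`, or with no candidate A, return no call (logged).

## Intron-retention coding consequences

For an annotated intron inside the CDS span of a transcript, the reading
frame at the insertion point comes from the CDS annotation; the retained
sequence is then scanned codon by codon, including codons straddling both
exon-intron junctions. A stop codon overlapping the intron gives
`in_frame_stop`; otherwise a frame-preserving intron (length ≡ 0 mod 3)
gives `no_ptc`; otherwise scanning continues through the downstream
coding sequence up to the annotated CDS end, and a stop ending strictly
before that end gives `frameshift_ptc_downstream` (a stop at the normal
termination point is not premature). Introns outside the CDS, or in
transcripts without CDS, are `frame_unavailable` — a deliberate
refinement that keeps "no PTC" distinct from "frame unknown". Controls
get a consequence call when CDS context exists, but the reported
in-frame-stop percentage uses event retained introns only.

## Statistics

Two-group comparisons use Welch's unequal-variance two-sided t test (the
safer default for "unpaired t tests", and asymptotically identical under
equal variances), with a Kolmogorov–Smirnov normality flag attached per
group for information — the test runs regardless. P-values are adjusted
across the whole summary table (Benjamini-Hochberg by default, Bonferroni
available) and verdicts — higher / lower / no significant difference, per
control set — are driven by the adjusted values at α = 0.05. Items with
an N inside any scoring window are excluded from strength comparisons but
keep their length/GC values. Threshold fractions (e.g. % of retained
introns shorter than 500 bp) use strict inequality.

## Motif enrichment

EM-style motif discovery is deliberately replaced by an exactly testable
discriminative statistic: for every k-mer (k = 5..8 by default; larger k
allowed but combinatorially sparse) present in ≥20% of foreground
sequences, the statistic is the difference in per-sequence presence
fractions between foreground (event E-I-E / E-I-E-I-E regions) and
background (the matched internal or external control constructs,
separately). The null permutes the sequence labels (default 1000
permutations), `p = (1 + #perm ≥ observed) / (1 + n_perm)`, BH-adjusted
across all tested k-mers. K-mers are integer-encoded so memory stays
bounded on kilobase-scale sequences.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
multi-exon protein-coding genes on a few chromosomes plus a mitochondrial
decoy; donor/acceptor windows drawn from generator weight matrices, with
event-cohort sites drawn from a matrix interpolated toward uniform until
the expected generator log-odds drops by the configured deficit (3 bits
donor, 1.5 bits acceptor by default; obligate GT/AG positions stay
fixed, so all introns remain canonical); retained-intron lengths from a
log-normal with median ~300 nt against ~1500 nt controls; exactly one
best-scoring branch point per intron at a drawn offset (competing
adenosines are mutated until the pipeline's own scanner provably returns
the planted offset — if a competitor sits inside an obligate window, the
window's intronic part is redrawn); CDS arranged so that an exact count
of retained-intron events (round(frac × n), default 93%) carries an
in-frame stop, with the remainder frame-preserving and provably
stop-free; p/FDR drawn strictly on the intended side of 0.05 (decoy rows
straddle the threshold, and one "NA" row per table exercises the
missing-value rule); and an expression table that puts the mitochondrial
decoys at the top of the ranking. A mirroring operation
reverse-complements every chromosome and flips all coordinates/strands;
it is an involution, and every transcript-orientation feature must be
identical on the mirrored data — the pipeline's strand-correctness
oracle. Generated CDS intervals include the terminal stop codon; with
annotations whose CDS excludes it, the downstream PTC scan simply ends a
codon earlier.

What the generator does **not** emulate: read-level noise in inclusion
estimates, correlated features (real intron length, GC and site strength
covary), non-canonical splice sites, alternative TSS/polyA structure,
overlapping genes, and NMD efficiency. Passing tests therefore show the
pipeline measures what it claims on data satisfying its assumptions, not
that the biological effect sizes of any particular dataset will look like
the planted ones.

## Problem sizes and determinism

Test fixtures use ~150 genes with ~20 retained-intron and ~16
skipped-exon events and an external pool of 60 — sizes chosen so the full
suite exercises every stage in well under a minute of pipeline time —
while the acceptance script uses 400 genes with 100 retained-intron
events and a pool of 150. Every sampling operation draws from one seeded
generator in a fixed stage order, so identical inputs + config + seed
give byte-identical outputs; effects are planted in generator-matrix bit
space, so recovered differences match in direction and approximate size
rather than exact bits (the trained scorer is not the generator matrix),
and acceptance checks direction and significance accordingly.
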