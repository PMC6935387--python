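# splicechar

Cis-feature characterization of mis-spliced pre-mRNAs. Given a genome
FASTA, a Gencode-style GTF, rMATS differential-splicing tables and a gene
expression table, `splicechar` asks *what distinguishes the introns that
are aberrantly retained and the exons that are aberrantly skipped* — in a
spliceosomal-deficiency setting such as an *EFTUD2* knockdown — *from the
introns and exons the spliceosome still handles correctly?*

It is written for transcriptomicists who have run rMATS on a case/control
RNA-seq comparison and want the downstream event characterization:

* **significance filtering** of rMATS events (keep p < 0.05 and FDR < 0.05)
  and direction calls (more vs less retention/skipping in the mutant);
* **matched control constructs** — internal exon-intron-exon (E-I-E) and
  exon-intron-exon-intron-exon (E-I-E-I-E) windows sampled from elsewhere
  in the same gene's reference transcript (the longest protein-coding
  transcript carrying a transcript support level), avoiding every event
  footprint, plus external controls from the most highly expressed
  non-mitochondrial, non-event genes;
* **splice-site strength** in MaxEntScan-compatible 9-mer donor / 23-mer
  acceptor windows, scored with positional log-odds models trained on the
  supplied annotation: `score(w) = Σ_p log2(probs[p][w_p] / bg[w_p])` in
  bits (published score tables can be plugged in for exact MaxEntScan
  parity);
* **branch points** via a consensus weight matrix plus polypyrimidine-tract
  term, reporting the BPS–3′SS distance;
* **coding consequences of intron retention** — in-frame stop, frameshift
  with a downstream premature termination codon, or a frame-preserving
  stop-free (potentially functional) intron;
* **group statistics** — Welch's unpaired t tests of every feature against
  both control sets, Bonferroni/Benjamini-Hochberg adjustment, qualitative
  verdict tables, threshold fractions (e.g. % of retained introns < 500 bp),
  and discriminative k-mer motif enrichment with a permutation null.

A synthetic-data generator plants all of these effects with a ground-truth
manifest, so the entire pipeline is testable without any external data.

## Worked example

```bash
python analysis/01_simulate.py --seed 1      # writes results/synthetic/
python analysis/02_characterize.py --seed 2  # writes results/characterization/
python analysis/03_calibration.py --seed 3   # writes results/calibration.tsv
```

The second step prints the retained-intron summary table (event groups IRI
= increased retention, DRI = decreased retention, vs internal/external
control introns ICI/ECI):

```
                    feature group                                    verdict
                donor_score   IRI  lower than external and internal controls
                donor_score   DRI  lower than external and internal controls
               focal_length   IRI  lower than external and internal controls
                  bp_offset   IRI higher than external and internal controls
     pct_with_in_frame_stop   IRI                                        94%
fraction_shorter_than_500bp   IRI                                        98%
fraction_shorter_than_500bp   ICI                                         0%
```

Reading: the planted 3-bit donor-site deficit is recovered as
significantly weaker donors for both event groups; retained introns are
far shorter than controls; their predicted branch points sit further from
the 3′ splice site; and ~93% of them carry an in-frame stop codon, so
retention would mostly feed nonsense-mediated decay. The calibration step
prints the null false-positive rate of the comparison (≈0.05) and its
power against the planted deficit (1.00 at n = 120 per group).

The same pipeline runs on real data through the CLI:

```bash
splicechar simulate --seed 42 --out demo/     # or point at your own inputs
splicechar run --config demo/config
```

The run config is a flat `key=value` file (genome, gtf, rmats_dir,
expression, outdir, g1_is_wildtype, seed, …). `g1_is_wildtype` is
mandatory: it states which condition was rMATS group 1, and every
direction-stratified result inverts with it.

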