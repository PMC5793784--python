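# splicefid

Splicing-fidelity analysis of splice-junction evidence in a small
(yeast-like) genome. The package quantifies the **splicing error
frequency (SEF)** of novel/cryptic splice junctions, contrasts fidelity
between strains, extracts intron sequence features and predicts SEF from
them:

- **`splicefid.genome`** — gene/transcript/intron models, GTF parsing
  (1-based GTF converted to 0-based half-open internally), FASTA access.
- **`splicefid.junctions`** — SJ.out.tab (STAR dialect) parsing/writing,
  junction filters (minimum supporting reads, overhang thresholds,
  mitochondrial-contig exclusion), and classification of novel junctions
  into alternative 5′/3′ splice sites (`u5/d5/u3/d3` with nt offsets),
  cryptic introns and exon skipping.
- **`splicefid.sef_quant`** — SEF for intronic events
  (novel/annotated junction reads, replicates pooled) and for cryptic
  introns in intron-less transcripts (reads/RPKM), RPKM/FPKM, read-class
  counting (junction/boundary/intron/exonic) and the pre-mRNA fraction,
  exon-skipping frequency, isoform ratio.
- **`splicefid.differential`** — two-sided Fisher's exact test per event
  (mutant vs WT), Benjamini–Hochberg FDR, fidelity-direction calls
  (defaults P < 0.01, FDR < 0.03) and RP/non-RP stratification.
- **`splicefid.seqfeatures`** — PWM splice-site/branch-point scores on
  fixed windows (5′SS 4+7, 3′SS 16+4, BP 7+3 nt), log2 probabilities
  linearly rescaled to 0–100, 84 k-mer (1- to 3-mer) frequencies,
  intron/branch-to-acceptor folding-energy proxy (base-pair
  maximization; pluggable external engine), and the per-event feature
  matrix (180 columns).
- **`splicefid.predictor`** — random-forest regression of log2 SEF with
  threefold target-stratified cross-validation, out-of-fold Pearson R
  and feature importances.
- **`splicefid.synthetic_data`** — deterministic generator of a genome,
  annotation, junction counts (negative-binomial annotated depth,
  binomial novel reads with planted per-event SEFs and strain fold
  changes) and labelled interval reads, with ground truth for every
  downstream stage.
- **`splicefid.pipeline` / `splicefid.cli`** — end-to-end orchestration
  and the `splicefid` command.

## CLI

```bash
# simulate a test universe (FASTA, GTF, SJ.out.tab per sample, truth JSON)
splicefid simulate --n-genes 60 --seed 1 --outdir sim/

# full demo run: simulate -> classify -> SEF -> contrasts -> features -> model
splicefid run-all --n-genes 60 --seed 1 --outdir run/

# analyse existing inputs
splicefid analyze --gtf annotation.gtf --fasta genome.fa \
    --sj WT_1=WT_1.SJ.out.tab --sj WT_2=WT_2.SJ.out.tab \
    --sj fast_1=fast_1.SJ.out.tab --sj fast_2=fast_2.SJ.out.tab \
    --outdir run/

# pre-mRNA fraction from an interval-read table
splicefid premrna --reads reads.tsv --gtf annotation.gtf --out classes.tsv

# summarize a run directory
splicefid report run/
```

A run directory contains `event_catalogue.tsv`, `sef_table.tsv`,
`contrasts.tsv`, `strata.tsv`, `feature_matrix.tsv`,
`oof_predictions.tsv`, `summary.json` and a `config_echo.json` recording
every threshold used. Outputs are byte-identical under a fixed seed.

## Notes on conventions

- Internal coordinates are 0-based half-open everywhere; GTF and
  SJ.out.tab columns are converted at the I/O boundary only.
- Replicates are pooled by summation before SEF ratios and Fisher
  tests (the ML choice for a binomial ratio; not the mean of
  per-replicate ratios).
- The cryptic-intron SEF (reads/RPKM) is depth-dependent as defined; a
  per-million-normalized variant is available but off by default.
- The FDR procedure is Benjamini–Hochberg; the two-sided Fisher P sums
  hypergeometric probabilities ≤ the observed table's (with a 1e-7
  relative tie slack).
- The folding ΔG is a base-pair-maximization proxy (min hairpin loop 3,
  −1 per pair, per-nt normalized); any external folding program can be
  plugged in via `fold_energy_proxy(engine=...)`.
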