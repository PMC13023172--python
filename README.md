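# screenbias

Representation-bias analysis for pooled CRISPR knockout screens.

Constructs with low initial plasmid (pDNA) abundance accumulate more
sampling noise through every bottleneck and sequencing step of a screen,
which inflates the magnitude of their gene effect scores and leads to false
essential-gene calls. This package provides:

- **screen_io** — readers/writers for guide libraries, count matrices,
  gene-effect score tables and gene lists; RPM normalization; per-sample QC
  (skew ratio, gRNA dropout) with the early-timepoint exclusion rule.
- **gene_effect** — log2 fold-change scoring against the library reference,
  per-gene aggregation, bottom-fraction essential calling (default 15%),
  common-essential recall, FNR/FPR curves, pairwise call overlap.
- **bias_diagnostics** — the core diagnostic: genes are split into
  equal-count bins by pDNA representation and the per-bin medians of the
  mean absolute gene effect are Spearman-correlated against per-bin mean
  pDNA; per-bin SD profiles, cross-library/replicate absolute-difference
  variants, LOESS display smoothing.
- **fp_estimation** — false-positive/negative accounting: essential-ratio
  threshold curves, elbow detection by maximum perpendicular distance to the
  endpoint chord, per-bin expected-vs-observed FP/FN estimation, and the
  essential vs non-essential pDNA ECDF/KS comparison.
- **correction** — per-bin z-scoring, low-representation filtering (with a
  matched random high-representation control), PCA pairwise-distance
  reports, grouped pairwise correlations and Wilcoxon testing.
- **simulate** — a generative screen model (log-normal representation,
  multiplicative fitness per population doubling, multinomial bottlenecks
  and sequencing) with ground truth for estimator validation.

## CLI

```sh
# simulate a default screen panel (2,000 genes, 500x coverage, 4 screens)
screenbias simulate --out-dir run/ --seed 1

# score, diagnose, estimate, correct, evaluate
screenbias score    --library run/library.tsv --counts run/counts.tsv \
                    --samples run/samples.tsv --out-dir run/
screenbias diagnose --library run/library.tsv --scores run/scores.tsv --out-dir run/
screenbias estimate --library run/library.tsv --scores run/scores.tsv --out-dir run/
screenbias correct  --library run/library.tsv --scores run/scores.tsv \
                    --mode zscore --out-dir run/
screenbias evaluate --library run/library.tsv --scores run/scores.tsv --out-dir run/
```

Outputs are tab-delimited tables and JSON reports; every command writes a
manifest (config hash, seed, version) next to its outputs, and reruns with
the same configuration are byte-identical.

## File formats

- Library: TSV/CSV with `construct_id, gene, is_control, pdna_count`.
- Count matrix: TSV/CSV, first column `construct_id`, one column per sample;
  sidecar metadata TSV with `sample, screen_id, replicate, timepoint_day,
  doublings, media`.
- Score matrix: TSV/CSV, first column `gene`, one column per screen.
- Gene list: plain text, one symbol per line.

Input delimiters are sniffed from the header; output is always
tab-delimited.
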