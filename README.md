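# lcrep

Analysis toolkit for immunoglobulin light-chain variable-domain repertoires:
germline V/J gene assignment, coverage classification, duplicate collapsing,
paralog-aware gene-usage enrichment, mutation-load statistics,
physicochemical scoring, and evaluation of external amyloidogenicity
predictions — with a synthetic repertoire generator providing ground truth
for everything.

## What it does

- **reference**: germline V/J reference sets (FASTA + TSV metadata) with
  paralog collapsing (proximal/distal IGKV copies counted under the proximal
  name), the merged `IGLJ2/IGLJ3` reporting label, and configurable CDR
  windows. A small bundled test reference (real IMGT gene names, synthetic
  sequences) makes the whole package runnable offline.
- **simulate**: cohorts of rearranged V–J sequences with configurable
  per-gene usage, per-residue substitution rate, Poisson indels, truncation,
  fragments and near-identical duplicates; deterministic under a seed, with
  a replayable edit script per record.
- **assign**: affine-gap BLOSUM62 alignment (global on the germline, free
  end gaps on the query) over all same-locus (V, J) template pairs; edit
  counting; coverage classes *complete* / *incomplete* (≥80 contiguous
  residues spanning all three CDR windows) / *excluded*; consensus-based
  duplicate collapsing with ambiguity exclusion.
- **mutation**: the length-normalised mutation statistic
  `100·(S/L + I/(L+I) + D/(L−D))` plus Kruskal–Wallis / rank-sum cohort
  comparisons with BH-FDR.
- **enrichment**: per-gene 2×2 odds ratios (equivalent to single-predictor
  logistic regression), Wald CIs, Haldane–Anscombe correction,
  Benjamini–Hochberg adjustment across both loci jointly, Pearson usage
  correlations.
- **physchem**: isoelectric point (EMBOSS pKa set, bisection) and
  Kyte–Doolittle GRAVY.
- **predeval**: confusion-matrix sensitivity/specificity/accuracy for
  externally produced amyloidogenicity calls.
- **table1 / pipeline / cli**: aggregation of the bundled published
  category-count table, and an end-to-end pipeline with a JSON run summary.

## CLI

```sh
lcrep run-all --seed 1 --out out/            # demo: 3 synthetic cohorts
lcrep table1                                  # aggregate the bundled count table
lcrep simulate --config cohorts.yaml --out sim/
lcrep assign --fasta sim/AL.fasta --metadata sim/AL.metadata.tsv --out assigned.tsv
lcrep usage --assignments assigned.tsv --cohorts AL,MM,control --out usage.tsv
lcrep enrich --usage-table usage.tsv --case AL --control MM --out enrichment.tsv
lcrep mutstats --assignments assigned.tsv --grouping locus --out mutstats.tsv
lcrep props --fasta sim/AL.fasta --out props.tsv
lcrep evaluate --predictions preds.tsv --labels labels.tsv --out metrics.tsv
```

All stages are deterministic under `--seed`; re-runs are byte-identical.

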