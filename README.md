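# synodeconv

Synovial transcriptome analysis toolkit for studying treatment response in
rheumatoid arthritis cohorts. It implements a complete multilevel pipeline —
preprocessing, differential expression, GO over-representation, cell-subset
deconvolution, and qPCR validation — together with a synthetic-data module
that generates ground-truth cohorts so every stage can be tested end to end
without any external downloads.

## What it does

- **synthetic data** (`synodeconv.synthetic`): cell-type reference profiles
  with planted marker genes; paired two-timepoint bulk cohorts built as
  convex mixtures of reference profiles on the linear intensity scale, with
  Beta-jittered cell fractions, planted differentially expressed genes,
  additive batch shifts, and Gaussian noise; GO annotations with planted
  enriched terms; Ct tables linearly linked to expression.
- **io** (`synodeconv.io`): validated readers/writers for TSV expression
  matrices, sample sheets, GMT gene sets, GO annotations, and Ct tables.
- **preprocess** (`synodeconv.preprocess`): log2 transform, quantile
  normalization (mean of order statistics, tie-safe, idempotent), and
  parametric empirical-Bayes batch adjustment (ComBat). The batch adjuster
  is validated to 1e-6 against output frozen from the published reference
  implementation (`tests/data/combat_reference_output.tsv`).
- **differential expression** (`synodeconv.diffexpr`): per-gene two-group
  t-tests (Welch by default, pooled or paired available), signed fold
  changes (2^Δ with the −1/r convention), Bonferroni correction, and the
  nominal-P + |FC| filter used to select genes for pathway analysis.
- **pathway enrichment** (`synodeconv.enrichment`): one-sided hypergeometric
  over-representation computed from first principles as an exact log-space
  tail sum, Bonferroni-controlled over the terms tested.
- **deconvolution** (`synodeconv.deconvolution`): the core method. A cell
  subset's contribution to a bulk sample is scored by the enrichment of its
  marker signature in the sample's ranked gene list: a running sum gains
  1/|S| at signature genes and loses 1/(N−|S|) elsewhere, and the score is
  the signed maximum deviation from zero (classic unweighted
  Kolmogorov–Smirnov GSEA statistic, exact integer-scaled arithmetic).
  Includes one-vs-rest signature derivation from reference profiles, group
  association tests, and paired longitudinal comparisons.
- **qPCR validation** (`synodeconv.qpcr`): 2^(−ΔΔCt) relative
  quantification and Pearson correlation against array-derived expression.
- **pipeline** (`synodeconv.pipeline` / CLI): one YAML config drives the
  whole analysis and emits deterministic TSV tables plus a `summary.json`.

## CLI

```bash
# full synthetic end-to-end run
synodeconv pipeline run --config config.yaml

# individual stages
synodeconv preprocess log2     --matrix raw.tsv --out log2.tsv
synodeconv preprocess quantile --matrix log2.tsv --out qn.tsv
synodeconv preprocess combat   --matrix qn.tsv --samples samples.tsv --out adj.tsv
synodeconv diffexpr --matrix adj.tsv --samples samples.tsv --contrast baseline --out de.tsv
synodeconv enrich --genes genes.txt --annotation go.tsv --universe universe.txt --out enr.tsv
synodeconv deconv score --matrix adj.tsv --signatures sigs.gmt --out scores.tsv
synodeconv deconv associate --scores scores.tsv --samples samples.tsv --timepoint week0 --out assoc.tsv
synodeconv qpcr --table ct.tsv --target CTLA4 --endogenous RPL11 --calibrator s1 --out ddct.tsv
```

A minimal synthetic config:

```yaml
seed: 1
output_dir: out
synthetic:
  n_genes: 2000
  n_responders: 8
  n_nonresponders: 3
  tph_fraction_resp: 0.05
  tph_fraction_nonresp: 0.15
  noise_sd: 0.3
  batches: {b1: 0.0, b2: 0.5}
thresholds: {p_nominal: 0.05, fc_threshold: 1.2, alpha: 0.05}
```

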