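# subtypekit

Cohort-aware breast cancer intrinsic molecular subtyping in Python:

* **Two classification engines.** A nearest-centroid (NC) engine with six
  centering strategies (cohort median, robust 5%/95% rescaling, ER-balanced
  subcohort medians — plain, iterative or PCA-guided — and subgroup-specific
  quantile centering), and a single-sample-predictor (SSP) engine that scores
  within-sample gene-pair order rules under a naive-Bayes model.
* **A ten-method registry** (`parker.original`, `genefu.scale`, `PCAPAM50`,
  `cIHC`, `cIHC.itr`, `genefu.robust`, `ssBC`, `ssBC.v2`, `AIMS`, `sspbc`)
  declared in a versioned YAML file; classifier parameters (centroid tables,
  quantile tables, rule sets) are user-supplied TSV model files.
* **AUTO method selection.** Quantitative gates on cohort composition decide
  which methods run: unselected cohorts with an ER+ percentage ≤ 39% or
  ≥ 69% route to the ER-deviated branch; subgroup-specific methods require
  minimum sizes (15 ER+ / 18 ER− or TN for `ssBC`; 8/8/9/9 per ER/HER2
  subgroup for `ssBC.v2`); SSP methods are always enabled. Every decision is
  audited with machine-readable reasons.
* **Method-specific normalization.** Raw RNA-seq counts become upper-quartile
  log2 CPM for NC methods and unscaled linear FPKM for SSP methods;
  pre-normalized log2 inputs pass through for NC and are back-transformed
  (2^x) for SSP. Probe-level matrices are collapsed to Entrez genes by
  largest interquartile range.
* **Concordance reporting.** Per-sample Shannon entropy (bits), pairwise
  unweighted Cohen's kappa, and accuracy against a reference column.
* **Synthetic benchmarking.** Toy model generation, a cohort simulator with
  controlled ER/HER2 composition, kappa-drop cutoff derivation, and an
  AUTO-vs-excluded benchmark harness.

## CLI

All subcommands are under a single entry point:

```sh
# write a synthetic cohort + toy model files
subtypekit --seed 1 simulate --n-genes 40 --n 118 --outdir demo/

# normalization route for a method family
subtypekit preprocess --expression counts.tsv --platform rnaseq_counts \
    --family NC --out normalized.tsv

# one method
subtypekit subtype --expression demo/expression.tsv --platform microarray \
    --method parker.original --centroids demo/centroids.tsv --out calls.tsv

# multi-method with AUTO selection and an audit trail
subtypekit --seed 1 --audit-out audit.json multi \
    --expression demo/expression.tsv --platform microarray \
    --clinical demo/clinical.tsv --cohort-type unselected --auto \
    --centroids demo/centroids.tsv --quantiles demo/quantiles.tsv \
    --ruleset demo/ruleset_AIMS.tsv --out calls.tsv --report-out report.json

# agreement statistics for an existing call matrix
subtypekit entropy --calls calls.tsv --out entropy.json

# simulation studies
subtypekit --seed 1 derive-cutoffs --method parker.original -r 100 --out cutoffs.json
subtypekit --seed 1 benchmark -r 25 --out benchmark.json
```

Expression TSVs are genes-in-rows / samples-in-columns (`--transpose` for
the other orientation); clinical TSVs carry `sample_id`, `er`, `pr`, `her2`
and an optional boolean `tn` column (a TN declaration is rejected unless
ER, PR and HER2 are all negative). Biomarker synonyms are case-insensitive:
`pos`/`positive`/`1`/`+` and `neg`/`negative`/`0`/`-`; anything else parses
as unknown.

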