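# Method registry, version 1.
#
# The branch membership encoded in assumption tags (conventional vs
# ER-deviated vs subtype-specific) is declarative so it can be corrected
# without a code change. Gates are minimum subgroup sizes keyed by clinical
# subgroup.
version: 1
methods:
  - name: parker.original
    family: NC
    centering: median
    correlation: spearman
    model: centroid
    tags: [conventional]
  - name: genefu.scale
    family: NC
    centering: median
    correlation: pearson
    model: centroid
    tags: [conventional]
  - name: PCAPAM50
    family: NC
    centering: pca_guided
    correlation: spearman
    model: centroid
    tags: [conventional]
  - name: cIHC
    family: NC
    centering: cihc
    correlation: spearman
    model: centroid
    tags: [er_deviated]
  - name: cIHC.itr
    family: NC
    centering: cihc_iterative
    correlation: spearman
    model: centroid
    tags: [er_deviated]
  - name: genefu.robust
    family: NC
    centering: robust_scale
    correlation: pearson
    model: centroid
    tags: [er_deviated]
  - name: ssBC
    family: NC
    centering: ssbc_quantile
    correlation: spearman
    model: centroid+quantile
    tags: [subtype_specific]
    gates:
      "ER+": 15
      "ER-": 18
      "TN": 18
  - name: ssBC.v2
    family: NC
    centering: ssbc_quantile
    correlation: spearman
    model: centroid+quantile
    tags: [subtype_specific]
    gates:
      "ER+/HER2-": 8
      "ER+/HER2+": 8
      "ER-/HER2+": 9
      "ER-/HER2-": 9
  - name: AIMS
    family: SSP
    model: ruleset
  - name: sspbc
    family: SSP
    model: ruleset
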