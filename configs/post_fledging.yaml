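# Adult (post-fledging) ageing-clock preset: merge complementary
# dinucleotides first, coverage-filter the merged sites, train on the exact
# universal-site intersection. Ages in years.
calls_dir: cohort
metadata: cohort/metadata.tsv
out_dir: runs/ageing
preset: post_fledging
seed: 1
qc_min_sites: 0          # raise to 2.5e6-scale values for real libraries
filter:
  min_coverage: 10
  max_coverage_percentile: 99.9
  mean_low: 0.05
  mean_high: 0.95
  min_sd: 0.05
clock:
  alpha: 0.2
  cv_folds: 10
run_enrichment: true
run_validation: false
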