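# Nestling (pre-fledging) developmental-clock preset: coverage-filter the
# per-strand records first, then merge; the common CpG panel comes from the
# age-stratified random subset search. Ages in days.
calls_dir: cohort
metadata: cohort/metadata.tsv
out_dir: runs/development
preset: pre_fledging
seed: 1
qc_min_sites: 0          # raise to 3e6-scale values for real libraries
filter:
  min_coverage: 10
  max_coverage_percentile: 99.9
  mean_low: 0.05
  mean_high: 0.95
  min_sd: 0.05
subset_search:
  n_groups: 4
  iterations: 500
  age_bins: 4
  seed: 1
clock:
  alpha: 0.2
  cv_folds: 10
run_enrichment: true
run_validation: true
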