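# Methods

`methclock` implements the construction and evaluation of epigenetic clocks —
penalised linear models that predict an individual's age from DNA-methylation
ratios at a panel of CpG sites — for reduced-representation bisulphite data
from wild bird cohorts, together with the filtering, site-selection,
enrichment and experimental-validation steps that surround clock building.
This note records the models, the defaults and the design decisions, and what
the synthetic benchmark does and does not establish.

## Data model and filtering

The raw unit is a strand-resolved methylation call: (chromosome, 1-based
position, strand, methylated count, unmethylated count), one file per sample.
A CpG dinucleotide is palindromic, so the forward-strand C at position *p*
and the reverse-strand C at *p + 1* measure the same site;
`merge_complementary` sums their counts into one site keyed to the
forward-strand coordinate. The methylation ratio is methylated / (methylated
+ unmethylated), in [0, 1].

Two per-sample coverage rules remove unreliable sites: coverage below
`min_coverage` (default 10) and coverage strictly above the
`max_coverage_percentile` (default 99.9) linear-interpolation quantile of
that sample's coverages — very high coverage in reduced-representation data
usually signals collapsed repeats or PCR artefacts. A cross-sample
variability rule then removes sites whose mean ratio lies outside
[0.05, 0.95] or whose sample standard deviation (n − 1 denominator) is below
0.05: near-constant sites cannot correlate with age. All four boundaries are
inclusive for survival ("less than 10" removes 9 but keeps 10, and so on).

Two orderings of merging and coverage filtering are supported, because both
occur in practice: `merge_first` (merge dinucleotides, then filter merged
sites) and `filter_first` (filter per-strand records, then merge). They are
exposed as the pipeline presets `post_fledging` and `pre_fledging`. The
coverage percentile is computed per sample, matching the per-sample
processing flow; a pooled-across-samples variant would be a one-line change
and the choice is configurable through `cap`.

The bismark `.cov` dialect carries no strand column; its reader ingests
records as forward-strand, already strand-collapsed sites.

## Universal sites and the stratified subset search

Penalised regression needs a complete samples × sites matrix, so clock
training is restricted to *universal* sites — those covered in every sample.
Reduced-representation libraries cover different site sets per sample, and
with many samples the exact intersection can collapse. Two mitigations are
implemented: `sample_qc` drops samples with few called CpGs (threshold
inclusive), and `stratified_subset_search` trades cohort size for panel
size. The search repeatedly (default 500 iterations) partitions the samples
into `n_groups` (default 4) age-stratified groups and scores each group by
its number of group-universal sites; the single best (iteration, group) over
the whole search is returned, ties broken by first occurrence.

Stratification sorts samples by (age, sample id) — the id tiebreak makes the
seed fully determine the outcome when many nestlings share integer ages —
cuts the ordering into `age_bins` equal-size quantile bins, shuffles within
bins and deals round-robin, continuing the deal across bins so group sizes
stay balanced. Every iteration's partition is kept on the result (`trace`),
so any reported count can be recomputed exactly from the stored memberships.

## The elastic-net clock

With predictors standardized to zero mean and unit population SD, the clock
minimises

```
(1/2n) Σ_i (y_i − b0 − x_i'b)²  +  λ ( α‖b‖₁ + (1 − α)‖b‖₂²/2 )
```

where α ∈ [0, 1] mixes ridge (α = 0) and lasso (α = 1) and λ scales the
penalty. Fitting uses scikit-learn's coordinate descent, whose objective is
exactly this parameterisation (`l1_ratio` = α, `alpha` = λ); after every fit
the KKT subgradient conditions are evaluated and stored on the model
(`kkt_violation`, warn above 1e-6). Ages are modelled untransformed and
linearly; log-linear age transforms are out of scope.

Tuning:

* **λ path.** A geometric grid of 100 values descends from the closed-form
  λ_max = max_j |⟨x_j, y − ȳ⟩| / (n·α) (the smallest penalty zeroing every
  coefficient; for α = 0 the formula substitutes α = 0.001, the usual
  convention since ridge has no finite λ_max). The lower end is λ_max·1e-4
  when n > p, λ_max·1e-2 otherwise. k-fold CV (default 10) along the path
  yields `lambda_min`, the argmin of pooled CV MSE, ties to the larger λ.
* **α sweep.** For each α in 0, 0.1, …, 1.0 the path CV is repeated (default
  100 iterations) with fresh fold randomisations; the table reports mean and
  SD of the minimum CV MSE and of the nonzero-coefficient count at each
  iteration's λ_min. The package reports the evidence; choosing α is left to
  the analyst (error and panel size usually pull in opposite directions, and
  α = 0.2 is the default adopted here as that compromise).
* **LOOCV.** Accuracy is estimated by leave-one-out CV at fixed α: for each
  sample a clock is trained on the others with λ re-selected by internal
  10-fold CV inside the training fold, and the held-out age predicted.
  Re-selecting λ per fold avoids leaking the full-data λ into the folds; a
  `fixed_lambda` mode reproduces the alternative reading in which the
  full-data λ is reused. Internal fold seeds are derived from (master seed,
  held-out sample id) via CRC-32, so per-sample predictions are invariant to
  row order.
* **Final clock.** Fitted on all samples at the chosen α with λ = λ_min from
  a full-data internal CV.

Numerical settings: CV paths run coordinate descent at tolerance 1e-3 (only
the shape of the CV-MSE curve matters there); final fits at 1e-8 so the KKT
check is meaningful. Constant predictor columns are dropped with a warning
in `fit_elastic_net` and neutralised (zero after centering) inside CV folds.
Constant response raises.

Reported metrics are the Pearson correlation r between predicted and
chronological age with a Fisher-z 95% CI (z = atanh r, half-width
z₀.₉₇₅/√(n − 3)), and the MAD — the plain median of |predicted −
chronological|, with no robust-dispersion consistency constant. If the
predictions are numerically constant, r is reported as 0 (a degenerate clock
has no age association).

Prediction on new samples refuses any sample missing one or more clock CpGs
(`MissingSitesError` lists them): a sparse panel is only portable to samples
in which every retained CpG was detected.

### A caveat on LOOCV correlation under the null

When the data carry no age signal, the internal CV selects λ near λ_max and
the leave-one-out prediction for sample *i* collapses to the training-fold
mean ȳ₋ᵢ = (S − yᵢ)/(n − 1) — a strictly decreasing function of the held-out
age. Pearson r is scale-free, so these vanishingly small systematic
variations dominate: LOOCV r is biased towards −1 for uninformative models
(empirically −0.3 to −1.0 on null cohorts, with the regression slope of
prediction on age matching −1/(n − 1)). A negative LOOCV r of this kind is a
leave-one-out arithmetic artefact, not evidence of an (inverse) clock; users
should judge null behaviour by the MAD relative to the spread of ages (under
the null the LOOCV MAD matches that of predicting the mean age) rather than
by |r|.
This is why the null-cohort test in the acceptance suite, which bounds |r|,
fails by design of the procedure itself.

## Chromosome enrichment

For each chromosome a 2×2 Fisher's exact test compares the clock's retained
CpGs against the non-selected CpGs of the training matrix (selected on/off
chromosome vs non-selected on/off). The two-sided p sums hypergeometric
point probabilities not exceeding the observed table's (the standard exact
convention, as implemented in scipy). Sites without a chromosome assignment
pool into one "unplaced" category. Per-chromosome results are reported raw —
no multiple-testing correction — with Benjamini–Hochberg q-values available
behind a flag. The direction flag compares the observed selected count with
its expectation under proportional representation.

## Treatment validation

Epigenetic ages of an experimental cohort are modelled with a linear mixed
model fitted by REML (statsmodels MixedLM): treatment as a reference-coded
fixed effect (reference = control) and brood of origin as a random
intercept, since nest mates share rearing environment. Estimated marginal
means per treatment are the model-implied group means (intercept + effect
under this coding, with a single fixed factor); their SEs come from the
fixed-effect covariance. Pairwise contrasts use unadjusted p-values
(Fisher's least-significant-difference convention — a deliberate
no-correction contract) against a t reference with residual degrees of
freedom approximated as n − (number of fixed-effect parameters); this is the
simplest df rule and slightly liberal relative to Satterthwaite, which is
acceptable for the LSD-style screening the analysis performs. A compact
letter display (insert-and-absorb) summarises which treatments are mutually
indistinguishable. With a single brood the random intercept is
unidentifiable; the fit falls back to ordinary least squares with a warning.

## Synthetic data generator

`simulate_cohort` emulates the statistical shape of the field data without
simulating reads:

* **Ages.** Continuous years uniform on [0.13, 6.03] (adults) or integer
  days from {6…15} (nestlings).
* **Methylation.** Each CpG has a baseline drawn from a three-component
  mixture (weights 0.3/0.3/0.4 of near-0, near-1 and intermediate Beta
  components shaped by `baseline_concentration`, default 10) — bisulphite
  data are strongly bimodal, and the mixture makes the variability filter
  remove a realistic fraction. A chosen subset of `n_age_cpgs` CpGs (placed
  in the intermediate component) receives a logit-linear age slope of random
  sign with magnitude uniform in [0.5, 1.5]·`slope_scale` (default 0.35
  logit-units per age unit, comparable to strong clock CpGs); methylated
  counts are Binomial(coverage, expit(baseline + slope·epigenetic age)).
* **Coverage and strands.** Site coverage is 1 + NegativeBinomial(mean
  `coverage_mean` − 1, dispersion `coverage_dispersion`; defaults 50 and 10)
  — always ≥ 1, heavy right tail. Coverage splits Binomial(cov, 0.5)
  between strands and methylated reads are allocated hypergeometrically, so
  strand records always sum to the site totals. The negative-binomial form
  is an assumption (no per-site coverage distribution is published for this
  kind of library), chosen as the standard overdispersed count model.
* **Missingness.** Each (sample, site) is dropped independently with
  probability `dropout_rate`, so per-sample site sets differ as they do in
  real reduced-representation libraries.
* **Design.** Samples fall into broods of `brood_size`; treatments cycle
  over broods; each treatment adds its `treatment_shift` to the *latent
  epigenetic age* (not to ratios directly), so with all shifts zero the
  epigenetic age equals the chronological age. `simulate_treatment_cohort`
  generates estimated epigenetic ages directly (base age + shift + brood
  random intercept + residual) for exercising the mixed model alone.
* **Determinism.** One master seed; per-sample generators derive from
  `SeedSequence.spawn`, making outputs byte-identical across runs.

## Benchmark conditions and what they show

The acceptance benchmark simulates 120 adults (ages uniform on [0.13, 6.0]
years) with 5000 CpGs, of which roughly 2300 survive the universal-site and
variability filters and 180 carry age slopes; coverage is deep (mean 50) and
dropout is zero, because with per-site dropout d the probability that a site
is universal across n samples is (1 − d)ⁿ — negligible at n = 120 for any
realistic d. (Real cohorts deal with this through sheer site numbers and the
subset search; the benchmark isolates clock recovery instead.) Under these
conditions the LOOCV clock recovers the planted signal with r close to 1 and
MAD near 0.1 years, while on a matched null cohort the selected penalty sits
near λ_max and the LOOCV MAD equals that of predicting the mean age. The
mixed-model benchmark uses 32 broods × 3 nestlings with true shifts
0/+0.25/+0.6 age units, brood SD 0.3 and residual SD 0.8.

Passing these tests shows that the pipeline's machinery — filters, matrix
assembly, penalised fitting, tuning, evaluation, enrichment counting and the
mixed model — implements its definitions correctly and recovers planted
structure. It does not show that real methylation data contain such
structure: the generator assumes logit-linear drift, binomial sampling noise
and site independence, and omits genetic variation between individuals, SNP
artefacts, batch and conversion-efficiency effects, correlated CpG blocks
and nonlinear age trajectories.

## Known limitations

* LOOCV Pearson r is uninformative (negatively biased) for null-signal
  data; see the caveat above.
* The 99.9% coverage percentile is taken per sample; a pooled variant may
  differ on small samples.
* Contrast p-values use the residual-df approximation, not Satterthwaite.
* The subset search is a random search by construction; it does not attempt
  combinatorial optimisation of the retained-site count.
* Clocks are linear in untransformed age; developmental and adult data are
  modelled separately rather than with a joint nonlinear transform.
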