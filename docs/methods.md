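# Methods

## Model and procedure

TMB is operated on as a raw count of nonsynonymous somatic mutations per
sample throughout; no per-megabase normalization is applied. The default
nonsynonymous vocabulary is {Missense_Mutation, Nonsense_Mutation,
Nonstop_Mutation, Splice_Site, Frame_Shift_Del, Frame_Shift_Ins,
In_Frame_Del, In_Frame_Ins, Translation_Start_Site}; it is configurable at
every entry point because MAF dialects differ in which terms they emit.
Counts are per mutation record — a gene hit twice in one sample contributes
2 — since the panel estimator sums mutation numbers; gene *frequency*, by
contrast, is presence-based (fraction of samples with ≥ 1 mutation).

**Candidate selection.** Only frequency-passing genes (≥ 10% by default)
are association-tested, so the multiplicity family is the tested set, not
the whole gene universe. The association test is a two-sided Mann–Whitney U
of WES-TMB in carriers vs wild-type. For group sizes both ≤ 8 the p-value
is exact: U is computed for every assignment of the pooled observations to
the two groups and the two-sided p is the fraction of assignments with U at
least as far from the null center mn/2 as observed (ties contribute ½ per
pair and are handled naturally by the enumeration). Larger groups use the
tie-corrected normal approximation (scipy). Adjustment is step-up
Benjamini–Hochberg by default, with Bonferroni and unadjusted modes.
By default only genes whose carriers have *higher* median TMB are kept
(`require_positive`): a sum-of-counts estimator is only helped by positively
informative genes; disabling it gives the literal "significant association"
reading.

**Panel search.** For each size k, `n_reps` independent uniform
without-replacement draws from the candidate pool (duplicates across
replicates permitted — they are independent redraws, no deduplication).
Each panel is scored by the Pearson r of its summed counts with WES-TMB,
vectorized over replicates. A replicate whose panel TMB is constant has no
defined r; it is recorded as NaN and can never win. Per-size random streams
are spawned from the master seed (`SeedSequence(seed, spawn_key=(k,))`), so
enlarging `n_reps` extends each stream without changing its prefix — the
best-so-far r can only improve. Ties in the maximum go to the first-drawn
replicate.

**Final selection.** Eligibility demands strict r > 0.9 (the threshold is a
parameter) *and* log-rank p < 0.05 for both OS and DFS when the best
panel's TMB is split at its median. The survival filter is applied only to
each size's best panel, keeping the number of survival tests O(#sizes).
The smallest eligible k is returned; an ineligible search returns a
diagnostics table (per-size max r, cutoff, both p-values), never an
exception. The median uses the lower-median convention for even n so the
cutoff is always an attained integer count; interpolated median is
available. Cutoffs learned in training are carried unchanged to validation
cohorts; `cutoff_scan` supports a per-cohort re-scan of the hazard ratio
over alternative cutoffs when re-calibration is contemplated.

**Survival statistics.** Kaplan–Meier, log-rank and Cox are delegated to
lifelines: product-limit estimator, two-group log-rank with hypergeometric
variance (1-df chi-square, two-sided), univariable Cox with the TMB-high
indicator and Efron tie handling (lifelines' default; the choice matters
only with heavily tied times). Monotone likelihood (all events in one
stratum) yields a flagged result with an unbounded CI rather than an
exception. Median survival is reported as missing when the curve never
crosses 0.5. All tests are two-sided at α = 0.05.

**Correlation inference.** The empirical p for a Pearson r permutes one
vector `n_perm` times and reports (1 + #{|r_perm| ≥ |r_obs|}) / (n_perm+1),
the add-one estimator that can never return 0. The augmentation test's
default p is a paired bootstrap over samples of r_augmented − r_base
(one-sided for an increase; degenerate resamples dropped), chosen over a
dependent-correlation z because the two estimates share the identical
sample and differ only in genes; the Meng–Rosenthal–Rubin z is available as
`method="steiger"`. The random-augmentation null reports the chosen set's
percentile with ties counted toward it (and `n_ties` reported), so a chosen
set equal to every null draw sits at percentile 1 rather than 0.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes, not any
particular dataset:

* latent burden λ_i ~ LogNormal(log 100, 0.8) — right-skewed, median ≈ 100,
  matching the order of magnitude of NSCLC exome counts;
* 150 of 2000 genes informative: counts ~ Poisson(λ_i · w_g),
  w_g ~ U(0.002, 0.006), giving per-gene frequencies ~15–45% and a
  planted-gene-sum correlation with WES-TMB above 0.9 at n = 500;
* 1850 noise genes: counts ~ Poisson(μ_g), μ_g ~ U(0, 0.3), independent of
  burden — some pass the frequency filter and must be rejected by the
  association test;
* survival: exponential event times with hazard
  h₀ · exp(β · 1[WES-TMB ≥ cohort median]), h₀ = 0.02/month for OS (median
  ≈ 35 months in the TMB-low group) and 1.5×/2× that for DFS/PFS;
  β = log 0.5 by default. A continuous mode applies β per standardized
  WES-TMB for cutoff-scan experiments. Censoring times are exponential with
  per-sample hazard h_i · c/(1−c), which makes the expected censored
  fraction exactly c (default 0.3) for exponential event times;
* response: P(DCB) = logistic(0 + 1.0 · standardized WES-TMB), giving
  ≈ 50% DCB prevalence as in advanced-line immunotherapy cohorts.

What the generator does **not** emulate: mutational signatures and
trinucleotide context, copy number, tumor purity, panel sequencing depth,
gene length (informative weights are not length-proportional), inter-gene
mutational correlation beyond the shared burden, or non-proportional
hazards. Tests passing on these cohorts therefore demonstrate the
statistical machinery — recovery of planted structure, calibration of the
tests, reproducibility — not clinical performance on real tumors.

Written cohorts fabricate MAF coordinates deterministically from gene index
and copy number, and cycle classifications through the nonsynonymous
vocabulary; downstream computation reads neither.

## Numerical choices and problem sizes

* Exact Mann–Whitney enumeration is limited to both groups ≤ 8
  (C(16,8) = 12 870 assignments); beyond that the tie-corrected normal
  approximation is accurate.
* Extreme-tail comparisons in enumerations and percentiles use a 1e-12
  slack to keep ties stable under floating-point.
* Bootstrap and permutation defaults (2000 resamples, 10 000 permutations)
  keep Monte-Carlo error below ~0.01 on p ≈ 0.05.
* The test suite and acceptance script run the full pipeline at the
  generator defaults (500 × 2000, sizes 1..30, 200 replicates per size) and
  scale unit fixtures down to a few hundred samples/genes; at the smaller
  scales the informative weight range is raised to keep the informative
  share of total burden comparable, since the achievable panel r depends on
  that ratio, not on n alone.
* Derived seeds are spawned via `numpy.random.SeedSequence` and kept below
  2³¹.

## Known limitations

* The candidate association test measures a gene against a WES-TMB total
  that includes the gene's own counts; with thousands of genes the
  self-contribution is negligible, but on very small gene universes it
  biases toward association.
* `select_final_panel` ranks eligible sizes only by k (sizes are unique per
  search); the CDS-length tie-break documented for equal-k candidates never
  triggers in the current single-search flow.
* The Cox wrapper fits one binary covariate; multivariable adjustment and
  competing risks are out of scope.
* Validation carries the training cutoff verbatim; when a validation
  cohort's burden scale differs (e.g. different capture size), the cutoff
  scan is the supported re-calibration path, not automatic rescaling.
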