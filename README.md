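# tmbpanel

Gene-panel estimation of tumor mutational burden (TMB) for NSCLC-style
somatic mutation data.

TMB — the count of nonsynonymous somatic mutations per tumor — predicts
response to immune checkpoint inhibitors and prognosis after resection, but
whole-exome sequencing (WES) is too expensive for routine use. A small,
carefully chosen gene panel whose summed mutation counts track WES-TMB can
stand in for it. `tmbpanel` implements the full construction and validation
pipeline for such panels, for bioinformaticians and biostatisticians working
with MAF-format mutation tables and clinical outcome data.

## Method

Given a gene × sample matrix of nonsynonymous mutation counts `C` and
WES-TMB `T_i = Σ_g C[g, i]`:

1. **Candidate genes.** Keep genes with mutation frequency ≥ 10% (fraction
   of samples with ≥ 1 mutation) whose carriers have significantly higher
   WES-TMB than wild-type samples (two-sided Mann–Whitney U,
   Benjamini–Hochberg adjusted, p_adj < 0.05, positive direction).
2. **Randomized panel search.** For each panel size k (default 1..30), draw
   many random k-gene subsets of the candidates; score each by the Pearson
   correlation r between its panel TMB `T̂_i = Σ_{g∈panel} C[g, i]` and
   WES-TMB; keep the best subset per size.
3. **Final selection.** Among sizes whose best panel achieves r > 0.9,
   dichotomize that panel's TMB at its median (lower-median convention, so
   the cutoff is an attained integer count) and require the TMB-high vs
   TMB-low split to separate both overall and disease-free survival
   (log-rank p < 0.05). The smallest eligible panel wins.
4. **Validation.** On an independent cohort, at the *training* cutoff:
   r(panel TMB, WES-TMB) with a permutation empirical p; Kaplan–Meier /
   log-rank / univariable Cox hazard ratios for OS/DFS/PFS; Mann–Whitney
   comparison of estimated TMB between immunotherapy response groups
   (durable clinical benefit vs none); hazard-ratio scans over alternative
   cutoffs; and panel-augmentation benchmarks against reference panels,
   including a random-gene-set null percentile.

A synthetic-cohort generator (`tmbpanel.simulate`) provides cohorts with the
assumed statistical structure — lognormal latent burden, Poisson gene
counts, exponential survival with a planted TMB hazard effect, logistic
response — plus ground-truth labels for parameter-recovery testing.

## Worked example

```python
from tmbpanel import (SimParams, simulate_cohort, select_candidates, wes_tmb,
                      search_by_size, select_final_panel, run_validation)

matrix, clinical, _ = simulate_cohort(SimParams(seed=7))
wes = wes_tmb(matrix)
cands = [c.gene_symbol for c in select_candidates(matrix, wes)]
summaries = search_by_size(matrix, wes, cands, sizes=range(1, 31), n_reps=200, seed=1)
sel = select_final_panel(summaries, matrix, clinical)
```

prints (via `examples/03_panel_search.py` and `04_validation.py`):

```
selected: 15-gene panel, r=0.9089, median cutoff 6 counts
OS log-rank p=2.04e-04, DFS log-rank p=7.61e-03
validation r = 0.9266 (empirical p = 0.0001)
DCB vs NDB: p = 1.89e-10 (medians 8 vs 5)
```

The 15-gene panel's summed mutation counts correlate with whole-exome TMB at
r ≈ 0.91 in training and generalize to a fresh cohort (r ≈ 0.93); splitting
patients at 6 counts separates survival, and estimated TMB is higher in
patients with durable benefit from checkpoint inhibition. The `examples/`
directory has one short script per capability; a thin CLI (`tmbpanel
simulate|select-candidates|search|estimate|run-validation|survival|compare-panels`)
wraps the same functions for shell use.

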