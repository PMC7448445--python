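"""Generate a synthetic NSCLC-like cohort and inspect its mutation burden.

The generator plants a heavy-tailed latent burden per sample, a set of
genes whose mutation counts track that burden ("informative"), and
burden-independent noise genes, plus survival and immunotherapy-response
labels tied to TMB.
"""

import numpy as np

from tmbpanel import SimParams, simulate_cohort, wes_tmb, write_cohort

params = SimParams(n_samples=300, n_genes=800, n_informative=60, seed=7)
matrix, clinical, truth = simulate_cohort(params)
wes = wes_tmb(matrix)

print(f"cohort: {matrix.shape[0]} genes x {matrix.shape[1]} samples, "
      f"{matrix.total()} nonsynonymous mutations")
print(f"WES-TMB: median {np.median(wes.values):.0f}, "
      f"IQR {np.percentile(wes.values, 25):.0f}-{np.percentile(wes.values, 75):.0f}, "
      f"max {wes.values.max()}")
print(f"planted informative genes: {len(truth.informative_genes)}")
n_dcb = sum(c.response == "DCB" for c in clinical)
print(f"response labels: {n_dcb} DCB / {len(clinical) - n_dcb} NDB")

paths = write_cohort(matrix, clinical, truth, "scratch/example_cohort")
print(f"wrote {', '.join(str(p) for p in paths.values())}")
# The median and IQR show the right-skewed burden distribution typical of
# NSCLC exomes; DCB prevalence near 50% reflects the logistic response link.
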