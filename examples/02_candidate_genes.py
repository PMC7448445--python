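"""Select candidate genes: mutation frequency >= 10% and association with TMB.

A gene qualifies when enough samples carry it and carriers have
significantly higher whole-exome TMB than wild-type samples (two-sided
Mann-Whitney U, Benjamini-Hochberg adjusted).
"""

from tmbpanel import SimParams, simulate_cohort, select_candidates, wes_tmb
from tmbpanel.candidates import candidate_table

matrix, clinical, truth = simulate_cohort(SimParams(seed=7))
wes = wes_tmb(matrix)

candidates = select_candidates(matrix, wes, freq_min=0.10, alpha=0.05)
planted = set(truth.informative_genes)
hits = sum(c.gene_symbol in planted for c in candidates)

print(f"{len(candidates)} candidate genes "
      f"({hits} of them truly burden-informative -> precision {hits/len(candidates):.2f})")
print(candidate_table(candidates).head(8).to_string(index=False))
# frequency is the fraction of mutated samples; p_adj < 0.05 plus a positive
# direction (higher median TMB in carriers) admits a gene to the panel search.
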