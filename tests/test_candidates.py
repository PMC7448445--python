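"""Frequency filter, Mann-Whitney association kernel and p-value adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmbpanel import (
    MutationMatrix,
    TMBVector,
    ValidationError,
    gene_frequency,
    select_candidates,
    adjust_pvalues,
    wes_tmb,
)
from tmbpanel.candidates import mann_whitney, mann_whitney_association
from conftest import make_matrix, random_matrix


class TestGeneFrequency:
    def test_fraction_of_mutated_samples(self):
        m = make_matrix({"A": {"s0": 1, "s1": 2}}, [f"s{i}" for i in range(10)])
        assert gene_frequency(m)["A"] == pytest.approx(0.2)

    def test_presence_not_count_semantics(self):
        m = make_matrix({"A": {"s0": 3}}, [f"s{i}" for i in range(10)])
        assert gene_frequency(m)["A"] == pytest.approx(0.1)

    def test_matches_independent_presence_scan(self):
        m = random_matrix(np.random.default_rng(2), n_genes=30)
        freq = gene_frequency(m)
        for g in m.genes:
            expect = np.mean([m.counts.at[g, s] >= 1 for s in m.samples])
            assert freq[g] == pytest.approx(expect)


def exact_oracle(x, y):
    """Independent enumeration oracle: U by pairwise comparison per assignment."""
    from itertools import combinations

    pooled = list(x) + list(y)
    m = len(x)
    centre = m * (len(pooled) - m) / 2
    u_obs = sum((a > b) + 0.5 * (a == b) for a in x for b in y)
    n_extreme = total = 0
    for comb in combinations(range(len(pooled)), m):
        gx = [pooled[i] for i in comb]
        gy = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u = sum((a > b) + 0.5 * (a == b) for a in gx for b in gy)
        total += 1
        n_extreme += abs(u - centre) >= abs(u_obs - centre) - 1e-12
    return u_obs, n_extreme / total


class TestMannWhitney:
    def test_separated_toy_exact_p(self):
        # all 6 assignments enumerated; only U=0 and U=4 are as extreme
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_identical_multisets_give_maximal_p(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=rng.integers(2, 8)).tolist()  # ties likely
        y = rng.integers(0, 6, size=rng.integers(2, 8)).tolist()
        u, p = mann_whitney(x, y)
        u_o, p_o = exact_oracle(x, y)
        assert u == pytest.approx(u_o)
        assert p == pytest.approx(p_o)

    def test_large_groups_use_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 40, size=30)
        y = rng.integers(5, 45, size=35)
        u, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1, 2])


class TestAssociation:
    def test_direction_follows_median_difference(self):
        m = make_matrix({"A": {"s0": 1, "s1": 1}}, [f"s{i}" for i in range(6)])
        wes = TMBVector(sample_ids=tuple(m.samples),
                        values=np.array([30, 40, 1, 2, 3, 4]), kind="wes")
        _, _, direction = mann_whitney_association(m, wes, "A")
        assert direction == "positive"

    def test_gene_mutated_everywhere_is_undefined(self):
        m = make_matrix({"A": {"s0": 1, "s1": 1}}, ["s0", "s1"])
        wes = wes_tmb(m)
        with pytest.raises(ValidationError, match="empty"):
            mann_whitney_association(m, wes, "A")


def bh_oracle(p):
    """Textbook step-up BH: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        for method in ("BH", "bonferroni"):
            assert adjust_pvalues([0.03], method=method)[0] == pytest.approx(0.03)

    def test_bonferroni_multiplies_by_family_size(self):
        out = adjust_pvalues([0.01, 0.02, 0.03], method="bonferroni")
        assert out == pytest.approx([0.03, 0.06, 0.09])

    def test_bh_matches_independent_step_up(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(1e-6, 1, size=100)
        assert adjust_pvalues(p, method="BH") == pytest.approx(bh_oracle(p))

    def test_out_of_range_p_rejected(self):
        for bad in ([0.0], [1.5], [-0.1]):
            with pytest.raises(ValidationError):
                adjust_pvalues(bad)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(1e-4, 1, size=50)
        for method in ("BH", "bonferroni"):
            assert (adjust_pvalues(p, method=method) >= p - 1e-15).all()


def cohort_with_planted_gene(n=50, n_mut=5, strong=True):
    """One gene mutated in exactly n_mut of n samples, with (or without) a
    strong WES-TMB shift in carriers; 'F' filler genes give WES its spread."""
    rng = np.random.default_rng(0)
    samples = [f"s{i}" for i in range(n)]
    base = rng.integers(10, 60, size=n)  # spread large vs the gene's own +1
    if strong:
        base[:n_mut] += 200
    counts = {"PLANT": {f"s{i}": 1 for i in range(n_mut)},
              "FILL": {f"s{i}": int(base[i]) for i in range(n)}}
    m = make_matrix(counts, samples)
    return m, wes_tmb(m)


class TestSelectCandidates:
    def test_frequency_boundary_inclusive(self):
        # frequency exactly 0.10 with a strong association passes
        m, wes = cohort_with_planted_gene(n=50, n_mut=5, strong=True)
        selected = {c.gene_symbol for c in select_candidates(m, wes, freq_min=0.10)}
        assert "PLANT" in selected

    def test_frequent_but_null_gene_excluded(self):
        m, wes = cohort_with_planted_gene(n=50, n_mut=25, strong=False)
        got = [c for c in select_candidates(m, wes) if c.gene_symbol == "PLANT"]
        assert got == []

    def test_monotone_filtering(self, small_cohort):
        matrix, _, _ = small_cohort
        wes = wes_tmb(matrix)
        base = {c.gene_symbol for c in select_candidates(matrix, wes, freq_min=0.10, alpha=0.05)}
        stricter_freq = {c.gene_symbol for c in select_candidates(matrix, wes, freq_min=0.20, alpha=0.05)}
        stricter_alpha = {c.gene_symbol for c in select_candidates(matrix, wes, freq_min=0.10, alpha=0.001)}
        assert stricter_freq <= base
        assert stricter_alpha <= base

    def test_result_sorted_and_deterministic(self, small_cohort):
        matrix, _, _ = small_cohort
        wes = wes_tmb(matrix)
        a = select_candidates(matrix, wes)
        b = select_candidates(matrix, wes)
        assert a == b
        p = [c.p_raw for c in a]
        assert p == sorted(p)
        assert set(c.gene_symbol for c in a) <= set(matrix.genes)

    def test_planted_genes_dominate_candidates(self, small_cohort):
        matrix, _, truth = small_cohort
        cands = select_candidates(matrix, wes_tmb(matrix))
        planted = set(truth.informative_genes)
        assert len(cands) > 0
        frac = sum(c.gene_symbol in planted for c in cands) / len(cands)
        assert frac >= 0.70

    def test_null_cohorts_pass_rate_bounded_by_alpha(self):
        # all genes burden-independent: BH keeps the expected discovery
        # fraction among tested genes at or below alpha
        from tmbpanel import SimParams, simulate_cohort

        rates = []
        for rep in range(50):
            params = SimParams(n_samples=60, n_genes=150, n_informative=0,
                               noise_rate_range=(0.05, 0.5), seed=1000 + rep)
            matrix, _, _ = simulate_cohort(params)
            wes = wes_tmb(matrix)
            n_tested = int((gene_frequency(matrix) >= 0.10).sum())
            if n_tested == 0:
                continue
            cands = select_candidates(matrix, wes, require_positive=False)
            rates.append(len(cands) / n_tested)
        assert np.mean(rates) <= 0.05
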