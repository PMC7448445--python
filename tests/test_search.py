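"""Randomized panel search, final selection and permutation p-values."""

from itertools import permutations

import numpy as np
import pytest

from tmbpanel import (
    Panel,
    ValidationError,
    empirical_pvalue_r,
    pearson_r,
    sample_random_panels,
    search_by_size,
    select_final_panel,
    wes_tmb,
)
from tmbpanel.search import UndefinedCorrelationError
from conftest import random_matrix


class TestPearsonR:
    def test_exact_linearity(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_closed_form_half(self):
        # cov = 0.5, sd_x = sd_y = 1 on these ranks
        assert pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        expect = np.cov(x, y)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert pearson_r(x, y) == pytest.approx(expect, abs=1e-12)


class TestSamplePanels:
    def test_full_size_is_a_forced_draw(self):
        panels = sample_random_panels(["A", "B", "C"], k=3, n_reps=5, seed=0)
        assert all(sorted(p.genes) == ["A", "B", "C"] for p in panels)

    def test_same_seed_identical_lists(self):
        a = sample_random_panels(list("ABCDEFG"), 3, 50, seed=9)
        b = sample_random_panels(list("ABCDEFG"), 3, 50, seed=9)
        assert [p.genes for p in a] == [p.genes for p in b]

    def test_oversized_k_rejected(self):
        with pytest.raises(ValidationError):
            sample_random_panels(["A", "B"], k=3, n_reps=1, seed=0)

    def test_pairs_drawn_uniformly(self):
        # 6 possible pairs from 4 genes; binomial bound at 3 standard errors
        n_reps = 6000
        panels = sample_random_panels(list("ABCD"), 2, n_reps, seed=4)
        freq = {}
        for p in panels:
            key = tuple(sorted(p.genes))
            freq[key] = freq.get(key, 0) + 1
        se = np.sqrt((1 / 6) * (5 / 6) / n_reps)
        assert len(freq) == 6
        for count in freq.values():
            assert abs(count / n_reps - 1 / 6) <= 3 * se


class TestSearchBySize:
    def test_full_candidate_set_reaches_r_one(self):
        m = random_matrix(np.random.default_rng(1))
        wes = wes_tmb(m)
        (summary,) = search_by_size(m, wes, m.genes, sizes=[len(m.genes)], n_reps=3, seed=0)
        assert summary.max_r == pytest.approx(1.0)

    def test_bit_reproducible_from_seed(self):
        m = random_matrix(np.random.default_rng(2))
        wes = wes_tmb(m)
        a = search_by_size(m, wes, m.genes, sizes=[2, 5], n_reps=20, seed=3)
        b = search_by_size(m, wes, m.genes, sizes=[2, 5], n_reps=20, seed=3)
        for sa, sb in zip(a, b):
            assert (sa.r_values == sb.r_values).all()
            assert sa.best_panel.genes == sb.best_panel.genes

    def test_max_dominates_mean_and_replicates(self):
        m = random_matrix(np.random.default_rng(3))
        wes = wes_tmb(m)
        for s in search_by_size(m, wes, m.genes, sizes=[1, 3, 7], n_reps=40, seed=5):
            assert s.max_r >= s.mean_r
            assert np.nanmax(s.r_values) == s.max_r
            assert (s.r_values[np.isfinite(s.r_values)] <= s.max_r + 1e-15).all()

    def test_extending_reps_never_lowers_max(self):
        # per-size streams extend: first n draws unchanged when n_reps grows
        m = random_matrix(np.random.default_rng(4))
        wes = wes_tmb(m)
        (short,) = search_by_size(m, wes, m.genes, sizes=[4], n_reps=30, seed=6)
        (long,) = search_by_size(m, wes, m.genes, sizes=[4], n_reps=60, seed=6)
        assert (long.r_values[:30] == short.r_values).all()
        assert long.max_r >= short.max_r

    def test_scoring_invariant_to_gene_order_within_panel(self):
        m = random_matrix(np.random.default_rng(7))
        wes = wes_tmb(m)
        from tmbpanel.tmb import estimate_panel_tmb

        genes = tuple(m.genes[2:7])
        fwd = estimate_panel_tmb(m, Panel(genes=genes))
        rev = estimate_panel_tmb(m, Panel(genes=genes[::-1]))
        assert (fwd.values == rev.values).all()


class TestFinalSelection:
    def test_single_passing_size_selected(self):
        from tmbpanel import SimParams, simulate_cohort

        # strong planted hazard effect so the survival filter has power
        matrix, clinical, truth = simulate_cohort(SimParams(
            n_samples=200, n_genes=400, n_informative=40,
            hazard_log_hr=np.log(0.3), censoring_rate=0.15, seed=6,
        ))
        wes = wes_tmb(matrix)
        cand = list(truth.informative_genes)
        summaries = search_by_size(matrix, wes, cand, sizes=[30], n_reps=60, seed=1)
        assert summaries[0].max_r > 0.9
        sel = select_final_panel(summaries, matrix, clinical)
        assert sel.selected and sel.k == 30
        assert sel.os_logrank_p < 0.05 and sel.dfs_logrank_p < 0.05
        assert sel.r_train == summaries[0].max_r

    def test_threshold_is_strict_no_selection_below(self, small_cohort):
        matrix, clinical, _ = small_cohort
        wes = wes_tmb(matrix)
        summaries = search_by_size(matrix, wes, matrix.genes, sizes=[1], n_reps=10, seed=2)
        sel = select_final_panel(summaries, matrix, clinical, r_threshold=1.0)
        assert not sel.selected
        assert sel.panel is None and sel.eligible_sizes == ()
        assert not sel.diagnostics.empty

    def test_eligibility_matches_independent_recomputation(self, small_cohort):
        matrix, clinical, truth = small_cohort
        from tmbpanel import estimate_panel_tmb, median_cutoff, stratify, logrank_test
        from tmbpanel.io import clinical_frame

        wes = wes_tmb(matrix)
        cand = list(truth.informative_genes)
        summaries = search_by_size(matrix, wes, cand, sizes=[5, 10, 20, 30], n_reps=50, seed=3)
        sel = select_final_panel(summaries, matrix, clinical)
        cf = clinical_frame(clinical)
        for s in summaries:
            if s.max_r <= 0.9:
                continue
            ptmb = estimate_panel_tmb(matrix, s.best_panel)
            strat = stratify(ptmb, median_cutoff(ptmb))
            ps = {}
            for endpoint in ("os", "dfs"):
                t = cf[f"{endpoint}_time"].to_numpy(dtype=float)
                e = cf[f"{endpoint}_event"].to_numpy(dtype=float)
                hi = strat.high_mask()
                ps[endpoint] = logrank_test(t[hi], e[hi], t[~hi], e[~hi])[1]
            expect_eligible = ps["os"] < 0.05 and ps["dfs"] < 0.05
            assert (s.k in sel.eligible_sizes) == expect_eligible


class TestEmpiricalPvalueR:
    def test_identity_gives_minimal_p(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        assert empirical_pvalue_r(x, x, n_perm=999, seed=0) == pytest.approx(1 / 1000)

    def test_matches_exhaustive_enumeration_at_n5(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=5), rng.normal(size=5)
        r_obs = pearson_r(x, y)
        perms = [np.corrcoef(x, np.array(p))[0, 1] for p in permutations(y)]
        p_exact = np.mean([abs(r) >= abs(r_obs) - 1e-12 for r in perms])
        n_perm = 20000
        p_mc = empirical_pvalue_r(x, y, n_perm=n_perm, seed=3)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) <= 3 * se + 2 / n_perm

    def test_seed_reproducible(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert empirical_pvalue_r(x, y, n_perm=500, seed=7) == empirical_pvalue_r(
            x, y, n_perm=500, seed=7
        )
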