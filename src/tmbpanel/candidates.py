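"""Candidate-gene selection: mutation frequency plus TMB-association filters.

A gene is a candidate for the panel search when (a) at least 10% of samples
carry a nonsynonymous mutation in it and (b) WES-TMB differs significantly
between mutated and wild-type carriers (two-sided Mann-Whitney U, adjusted
for multiplicity across the tested genes).  By default only genes whose
mutation indicates a *higher* burden are kept, since a sum-of-counts
estimator is only helped by positively informative genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MutationMatrix, ValidationError
from .tmb import TMBVector

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateGene",
    "gene_frequency",
    "mann_whitney",
    "mann_whitney_association",
    "adjust_pvalues",
    "select_candidates",
    "candidate_table",
]


@dataclass(frozen=True)
class CandidateGene:
    """Per-gene frequency and TMB-association test result."""

    gene_symbol: str
    frequency: float
    u_stat: float
    p_raw: float
    p_adj: float
    direction: Literal["positive", "negative"]
    median_tmb_mut: float
    median_tmb_wt: float


def gene_frequency(matrix: MutationMatrix) -> pd.Series:
    """Fraction of samples carrying >= 1 mutation in each gene (presence, not count)."""
    if matrix.shape[1] == 0:
        raise ValidationError("gene frequency undefined without samples")
    freq = (matrix.counts.to_numpy() >= 1).mean(axis=1)
    return pd.Series(freq, index=matrix.genes, name="frequency")


def _pairwise_gt(values: np.ndarray) -> np.ndarray:
    """G[i, j] = 1 if v_i > v_j, 0.5 if tied, 0 otherwise."""
    v = values[:, None]
    return (v > values[None, :]).astype(float) + 0.5 * (v == values[None, :])


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for group x: #{x_i > y_j} + 0.5 #{ties}."""
    return float(((x[:, None] > y[None, :]).sum()) + 0.5 * (x[:, None] == y[None, :]).sum())


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_max: int = 8
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of ``x`` vs ``y``; returns (U_x, p).

    When both group sizes are <= ``exact_max`` the p-value is exact: U is
    computed for every group assignment (every way of choosing which of the
    pooled observations form group x) and the two-sided p is the fraction of
    assignments whose U lies at least as far from the null centre mn/2 as the
    observed one.  Ties are handled naturally by the enumeration (0.5 per
    tied pair).  Larger groups use the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.shape[0], y.shape[0]
    if m == 0 or n == 0:
        raise ValidationError("Mann-Whitney requires two non-empty groups")
    u_obs = _u_statistic(x, y)
    if m <= exact_max and n <= exact_max:
        pooled = np.concatenate([x, y])
        G = _pairwise_gt(pooled)
        N = m + n
        centre = m * n / 2.0
        d_obs = abs(u_obs - centre)
        total = 0
        extreme = 0
        idx_all = np.arange(N)
        for comb in combinations(range(N), m):
            in_x = np.zeros(N, dtype=bool)
            in_x[list(comb)] = True
            u = G[np.ix_(idx_all[in_x], idx_all[~in_x])].sum()
            total += 1
            if abs(u - centre) >= d_obs - 1e-12:
                extreme += 1
        return u_obs, extreme / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def mann_whitney_association(
    matrix: MutationMatrix, wes: TMBVector, gene: str
) -> tuple[float, float, str]:
    """Association of a gene's mutation status with WES-TMB.

    Splits samples into mutated (count >= 1) and wild-type and compares their
    WES-TMB with a two-sided Mann-Whitney U test.  Returns
    ``(u_stat, p_raw, direction)`` where direction is the sign of the median
    TMB difference, mutated minus wild-type (ties broken by the mean
    difference).
    """
    if gene not in matrix.counts.index:
        raise ValidationError(f"gene {gene!r} not in matrix")
    if tuple(matrix.samples) != tuple(wes.sample_ids):
        raise ValidationError("matrix and WES-TMB vector must share the same samples")
    mutated = matrix.counts.loc[gene].to_numpy() >= 1
    tmb_mut = wes.values[mutated].astype(float)
    tmb_wt = wes.values[~mutated].astype(float)
    if tmb_mut.size == 0 or tmb_wt.size == 0:
        raise ValidationError(f"gene {gene!r}: mutated or wild-type group is empty")
    u, p = mann_whitney(tmb_mut, tmb_wt)
    med_mut, med_wt = float(np.median(tmb_mut)), float(np.median(tmb_wt))
    if med_mut != med_wt:
        direction = "positive" if med_mut > med_wt else "negative"
    else:
        direction = "positive" if tmb_mut.mean() >= tmb_wt.mean() else "negative"
    return u, p, direction


def adjust_pvalues(
    p_raw: Sequence[float], method: Literal["BH", "bonferroni", "none"] = "BH"
) -> np.ndarray:
    """Multiplicity adjustment (step-up Benjamini-Hochberg or Bonferroni).

    Input order is preserved.  Raw p-values must lie in (0, 1].
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in (0, 1]")
    if method == "none":
        return p.copy()
    sm_method = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=sm_method)[1]


def select_candidates(
    matrix: MutationMatrix,
    wes: TMBVector,
    freq_min: float = 0.10,
    alpha: float = 0.05,
    require_positive: bool = True,
    adjust_method: Literal["BH", "bonferroni", "none"] = "BH",
) -> list[CandidateGene]:
    """Genes with frequency >= ``freq_min`` and adjusted association p < ``alpha``.

    Only frequency-passing genes are tested (the adjustment family is the
    tested set).  Genes mutated in every sample, or whose test is otherwise
    undefined, are skipped with a warning.  The result is sorted by raw
    p-value ascending, ties broken by gene symbol.
    """
    freq = gene_frequency(matrix)
    tested = [g for g in matrix.genes if freq[g] >= freq_min]
    rows: list[tuple[str, float, float, float, str, float, float]] = []
    skipped = 0
    for g in tested:
        try:
            u, p, direction = mann_whitney_association(matrix, wes, g)
        except ValidationError:
            skipped += 1
            continue
        mutated = matrix.counts.loc[g].to_numpy() >= 1
        med_mut = float(np.median(wes.values[mutated]))
        med_wt = float(np.median(wes.values[~mutated]))
        rows.append((g, float(freq[g]), u, p, direction, med_mut, med_wt))
    if skipped:
        logger.warning("%d gene(s) skipped: one association group was empty", skipped)
    if not rows:
        logger.warning("no genes passed the frequency filter; candidate set is empty")
        return []
    p_adj = adjust_pvalues([r[3] for r in rows], method=adjust_method)
    out = [
        CandidateGene(
            gene_symbol=g, frequency=f, u_stat=u, p_raw=p, p_adj=float(pa),
            direction=direction, median_tmb_mut=mm, median_tmb_wt=mw,
        )
        for (g, f, u, p, direction, mm, mw), pa in zip(rows, p_adj)
        if pa < alpha and (direction == "positive" or not require_positive)
    ]
    out.sort(key=lambda c: (c.p_raw, c.gene_symbol))
    if not out:
        logger.warning("no genes passed the significance filter; candidate set is empty")
    return out


def candidate_table(candidates: Sequence[CandidateGene]) -> pd.DataFrame:
    """Candidate genes as a report DataFrame (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "gene": c.gene_symbol,
                "frequency": c.frequency,
                "u_stat": c.u_stat,
                "p_raw": c.p_raw,
                "p_adj": c.p_adj,
                "direction": c.direction,
                "median_tmb_mut": c.median_tmb_mut,
                "median_tmb_wt": c.median_tmb_wt,
            }
            for c in candidates
        ]
    )
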