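"""Benchmarking a panel against reference panels (e.g. large commercial CGPs).

Three questions: how well do two panels' TMB estimates agree with WES-TMB
and with each other; does *adding* a gene set to a reference panel
significantly raise its correlation with WES-TMB (paired bootstrap over
samples, with Steiger's dependent-correlation z as an alternative); and how
does a chosen added set rank against random added sets of the same size
drawn from a gene pool (the random-augmentation null percentile).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .io import MutationMatrix, Panel, ValidationError
from .tmb import TMBVector, estimate_panel_tmb
from .search import pearson_r, sample_random_panels

logger = logging.getLogger(__name__)

__all__ = [
    "AugmentationResult",
    "panel_overlap",
    "union_panel",
    "compare_panel_correlations",
    "augmentation_test",
    "random_augmentation_null",
]


@dataclass(frozen=True)
class AugmentationResult:
    """Correlation gain from augmenting a base panel, with optional null."""

    base_panel: str
    added_genes: int
    r_base: float
    r_augmented: float
    delta_r: float
    p_delta: Optional[float] = None
    null_r: Optional[np.ndarray] = field(default=None, repr=False)
    percentile_of_chosen: Optional[float] = None
    n_ties: Optional[int] = None


def panel_overlap(a: Panel, b: Panel) -> list[str]:
    """Genes shared by both panels, in ``a``'s order."""
    in_b = set(b.genes)
    return [g for g in a.genes if g in in_b]


def union_panel(base: Panel, added: Panel, name: Optional[str] = None) -> Panel:
    """Set union of two panels (overlapping genes counted once), base order first."""
    extra = [g for g in added.genes if g not in set(base.genes)]
    return Panel(genes=tuple(base.genes) + tuple(extra), name=name or f"{base.name}+{added.name}")


def compare_panel_correlations(
    matrix: MutationMatrix, wes: TMBVector, panel_a: Panel, panel_b: Panel
) -> tuple[float, float, float]:
    """(r_a, r_b, r_ab): each panel's TMB vs WES-TMB, and vs each other."""
    if len(panel_a) == 0 or len(panel_b) == 0:
        raise ValidationError("panels must be non-empty")
    tmb_a = estimate_panel_tmb(matrix, panel_a).values.astype(float)
    tmb_b = estimate_panel_tmb(matrix, panel_b).values.astype(float)
    w = wes.values.astype(float)
    return pearson_r(tmb_a, w), pearson_r(tmb_b, w), pearson_r(tmb_a, tmb_b)


def _steiger_p(r_aw: float, r_bw: float, r_ab: float, n: int) -> float:
    """Dependent-correlation z test (Meng-Rosenthal-Rubin form of Steiger's
    test) for two correlations sharing variable w; one-sided for
    r_aw > r_bw."""
    rbar2 = (r_aw**2 + r_bw**2) / 2.0
    if rbar2 >= 1 or n <= 3:
        return float("nan")
    f = min((1 - r_ab) / (2 * (1 - rbar2)), 1.0)
    h = (1 - f * rbar2) / (1 - rbar2)
    z = (np.arctanh(r_aw) - np.arctanh(r_bw)) * np.sqrt((n - 3) / (2 * (1 - r_ab) * h))
    return float(stats.norm.sf(z))


def augmentation_test(
    matrix: MutationMatrix,
    wes: TMBVector,
    base: Panel,
    added: Panel,
    n_boot: int = 2000,
    seed: int = 0,
    method: Literal["bootstrap", "steiger"] = "bootstrap",
) -> AugmentationResult:
    """Does adding ``added`` to ``base`` raise the correlation with WES-TMB?

    The augmented panel is the set union.  The default p-value is a paired
    bootstrap over samples: resample samples with replacement, recompute both
    correlations on each resample, and report the fraction of resamples where
    the gain (r_augmented - r_base) is <= 0 (one-sided for an increase).
    Resamples where either correlation is undefined (constant vector) are
    dropped.  ``method="steiger"`` uses Steiger's z for dependent
    correlations instead.
    """
    aug = union_panel(base, added)
    if len(aug) == 0:
        raise ValidationError("augmented panel is empty")
    tmb_base = estimate_panel_tmb(matrix, base, allow_empty=True).values.astype(float)
    tmb_aug = estimate_panel_tmb(matrix, aug).values.astype(float)
    w = wes.values.astype(float)
    r_base = pearson_r(tmb_base, w)
    r_aug = pearson_r(tmb_aug, w)
    delta = r_aug - r_base

    if set(added.genes) <= set(base.genes):
        # union unchanged: no gain possible, p is maximal by construction
        return AugmentationResult(
            base_panel=base.name, added_genes=0, r_base=r_base,
            r_augmented=r_aug, delta_r=0.0, p_delta=1.0,
        )

    if method == "steiger":
        r_ab = pearson_r(tmb_base, tmb_aug)
        p = _steiger_p(r_aug, r_base, r_ab, n=w.shape[0])
    else:
        rng = np.random.default_rng(seed)
        n = w.shape[0]
        deltas = np.empty(n_boot)
        deltas.fill(np.nan)
        for i in range(n_boot):
            idx = rng.integers(0, n, size=n)
            wb, b_b, a_b = w[idx], tmb_base[idx], tmb_aug[idx]
            if np.ptp(wb) == 0 or np.ptp(b_b) == 0 or np.ptp(a_b) == 0:
                continue
            rb = np.corrcoef(b_b, wb)[0, 1]
            ra = np.corrcoef(a_b, wb)[0, 1]
            deltas[i] = ra - rb
        valid = deltas[np.isfinite(deltas)]
        if valid.size == 0:
            raise ValidationError("all bootstrap resamples were degenerate")
        p = float((valid <= 0).mean())

    return AugmentationResult(
        base_panel=base.name,
        added_genes=len(set(added.genes) - set(base.genes)),
        r_base=r_base, r_augmented=r_aug, delta_r=delta, p_delta=p,
    )


def random_augmentation_null(
    matrix: MutationMatrix,
    wes: TMBVector,
    base: Panel,
    pool: Sequence[str],
    chosen: Panel,
    k: int = 23,
    n_reps: int = 1000,
    seed: int = 0,
) -> AugmentationResult:
    """Percentile of a chosen added gene set against random same-size additions.

    Draws ``n_reps`` k-gene sets from ``pool``, scores r(base ∪ draw, WES-TMB)
    for each to form the null distribution, and reports the chosen set's
    percentile as the fraction of null draws it is at least as good as
    (ties count toward the percentile and are documented in ``n_ties``).
    ``base`` may be empty (standalone-panel reading); the default mirrors
    augmented comparisons.
    """
    if k > len(pool):
        raise ValidationError(f"k={k} exceeds pool size {len(pool)}")
    aug_chosen = union_panel(base, chosen, name="chosen")
    tmb_chosen = estimate_panel_tmb(matrix, aug_chosen).values.astype(float)
    w = wes.values.astype(float)
    r_chosen = pearson_r(tmb_chosen, w)
    r_base = (
        pearson_r(estimate_panel_tmb(matrix, base).values.astype(float), w)
        if len(base) else float("nan")
    )
    draws = sample_random_panels(pool, k, n_reps, seed)
    counts = matrix.counts.to_numpy()
    gene_pos = {g: i for i, g in enumerate(matrix.genes)}
    base_idx = [gene_pos[g] for g in base.genes if g in gene_pos]
    base_tmb = counts[base_idx].sum(axis=0) if base_idx else np.zeros(len(w))
    null_r = np.empty(n_reps)
    wc = w - w.mean()
    wn = np.linalg.norm(wc)
    for i, d in enumerate(draws):
        extra = [gene_pos[g] for g in d.genes if g not in set(base.genes)]
        t = (base_tmb + counts[extra].sum(axis=0)).astype(float)
        tc = t - t.mean()
        tn = np.linalg.norm(tc)
        null_r[i] = (tc @ wc) / (tn * wn) if tn > 0 else np.nan
    valid = null_r[np.isfinite(null_r)]
    n_less = int((valid < r_chosen - 1e-12).sum())
    n_ties = int((np.abs(valid - r_chosen) <= 1e-12).sum())
    return AugmentationResult(
        base_panel=base.name,
        added_genes=k,
        r_base=r_base,
        r_augmented=r_chosen,
        delta_r=r_chosen - r_base if np.isfinite(r_base) else float("nan"),
        null_r=null_r,
        percentile_of_chosen=(n_less + n_ties) / valid.size if valid.size else float("nan"),
        n_ties=n_ties,
    )
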