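"""Randomized fixed-size panel search against WES-TMB.

For each panel size k, draw many uniform k-gene subsets of the candidate
genes, score each subset by the Pearson correlation of its panel-estimated
TMB with WES-TMB, and keep the best subset per size.  The final panel is the
smallest size whose best subset both exceeds the correlation threshold
(r > 0.9 by default) and stratifies the training cohort into groups with
significantly different overall and disease-free survival at its median
cutoff.  Correlation significance is assessed by a permutation empirical
p-value.

Every draw is reproducible from a single integer seed; per-size streams are
spawned from it so enlarging the replicate count only extends each stream
(the first n draws are unchanged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MutationMatrix, Panel, ClinicalRecord, ValidationError, clinical_frame
from .tmb import TMBVector, estimate_panel_tmb, median_cutoff, stratify

logger = logging.getLogger(__name__)

__all__ = [
    "UndefinedCorrelationError",
    "SizeSearchSummary",
    "FinalSelection",
    "pearson_r",
    "sample_random_panels",
    "search_by_size",
    "select_final_panel",
    "empirical_pvalue_r",
    "search_table",
]


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (constant vector or length < 3)."""


@dataclass(frozen=True)
class SizeSearchSummary:
    """Resampling results for one panel size k."""

    k: int
    n_reps: int
    r_values: np.ndarray  # per-replicate r; NaN where a panel's TMB was constant
    mean_r: float
    max_r: float
    best_panel: Panel
    seed: int


@dataclass(frozen=True)
class FinalSelection:
    """Outcome of the survival-filtered smallest-panel selection.

    When no size is eligible, ``panel`` is None and ``diagnostics`` explains
    why each evaluated size failed (its max r and the two log-rank p-values).
    """

    panel: Optional[Panel]
    k: Optional[int]
    r_train: Optional[float]
    cutoff: Optional[float]
    os_logrank_p: Optional[float]
    dfs_logrank_p: Optional[float]
    eligible_sizes: tuple[int, ...]
    diagnostics: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    @property
    def selected(self) -> bool:
        return self.panel is not None


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise UndefinedCorrelationError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def _rng_for_size(seed: int, k: int) -> np.random.Generator:
    # one independent, extendable stream per panel size
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(k,)))


def sample_random_panels(
    candidates: Sequence[str],
    k: int,
    n_reps: int,
    seed: int | np.random.Generator,
) -> list[Panel]:
    """Draw ``n_reps`` independent uniform k-gene subsets of ``candidates``.

    Replicates are independent redraws: duplicate panels across replicates
    are permitted.  Fully reproducible from the seed.
    """
    cand = list(candidates)
    if k > len(cand):
        raise ValidationError(f"panel size {k} exceeds candidate pool size {len(cand)}")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    panels = []
    for i in range(n_reps):
        genes = rng.choice(cand, size=k, replace=False)
        panels.append(Panel(genes=tuple(genes), name=f"rand_k{k}_rep{i}"))
    return panels


def _score_panels(
    counts: np.ndarray,
    gene_pos: dict[str, int],
    panels: Sequence[Panel],
    wes_values: np.ndarray,
) -> np.ndarray:
    """Pearson r of each panel's TMB with WES-TMB, vectorized; NaN if constant."""
    idx = np.array([[gene_pos[g] for g in p.genes] for p in panels])
    ptmb = counts[idx].sum(axis=1).astype(float)  # (n_panels, n_samples)
    w = wes_values.astype(float)
    wc = w - w.mean()
    wn = np.linalg.norm(wc)
    tc = ptmb - ptmb.mean(axis=1, keepdims=True)
    tn = np.linalg.norm(tc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (tc @ wc) / (tn * wn)
    return r


def search_by_size(
    matrix: MutationMatrix,
    wes: TMBVector,
    candidates: Sequence[str],
    sizes: Sequence[int] = range(1, 31),
    n_reps: int = 1000,
    seed: int = 0,
) -> list[SizeSearchSummary]:
    """For each size k, draw ``n_reps`` random candidate panels and score them.

    Scoring is the Pearson r between the panel-estimated TMB and WES-TMB.
    A replicate whose panel TMB is constant has no defined r; it is recorded
    as NaN (with a warning) and can never be the best panel.  Ties in the
    maximum are broken by the first-drawn replicate.
    """
    cand = list(candidates)
    missing = [g for g in cand if g not in matrix.counts.index]
    if missing:
        raise ValidationError(f"candidates not in matrix: {missing[:10]}")
    if tuple(matrix.samples) != tuple(wes.sample_ids):
        raise ValidationError("matrix and WES-TMB vector must share the same samples")
    counts = matrix.counts.to_numpy()
    gene_pos = {g: i for i, g in enumerate(matrix.genes)}
    summaries = []
    for k in sizes:
        rng = _rng_for_size(seed, k)
        panels = sample_random_panels(cand, k, n_reps, rng)
        r = _score_panels(counts, gene_pos, panels, wes.values)
        n_nan = int(np.isnan(r).sum())
        if n_nan:
            logger.warning("size %d: %d/%d replicates had undefined r (constant panel TMB)", k, n_nan, n_reps)
        if n_nan == n_reps:
            raise UndefinedCorrelationError(f"size {k}: every replicate's panel TMB was constant")
        best_i = int(np.nanargmax(r))
        best = Panel(genes=panels[best_i].genes, name=f"best_k{k}")
        summaries.append(
            SizeSearchSummary(
                k=k, n_reps=n_reps, r_values=r,
                mean_r=float(np.nanmean(r)), max_r=float(np.nanmax(r)),
                best_panel=best, seed=seed,
            )
        )
    return summaries


def select_final_panel(
    summaries: Sequence[SizeSearchSummary],
    matrix: MutationMatrix,
    clinical: Sequence[ClinicalRecord],
    r_threshold: float = 0.9,
    survival_alpha: float = 0.05,
    cutoff_convention: str = "lower",
) -> FinalSelection:
    """Pick the smallest panel that estimates TMB well *and* stratifies survival.

    Among sizes whose best panel achieves max r strictly above
    ``r_threshold``, each best panel's estimated TMB is dichotomised at its
    median cutoff and the TMB-high vs TMB-low groups are compared by the
    log-rank test on OS and on DFS; a size is eligible when both p-values
    fall below ``survival_alpha``.  The eligible size with the fewest genes
    wins.  When nothing is eligible a no-selection result with per-size
    diagnostics is returned, never an exception.
    """
    from .survival import logrank_test  # deferred: survival imports candidates

    cf = clinical_frame(clinical)
    diag_rows = []
    eligible: list[tuple[int, dict]] = []
    for s in sorted(summaries, key=lambda s: s.k):
        row: dict = {"k": s.k, "max_r": s.max_r, "passed_r": s.max_r > r_threshold,
                     "cutoff": np.nan, "os_logrank_p": np.nan, "dfs_logrank_p": np.nan,
                     "eligible": False}
        if s.max_r > r_threshold:
            ptmb = estimate_panel_tmb(matrix, s.best_panel)
            cut = median_cutoff(ptmb, convention=cutoff_convention)
            strat = stratify(ptmb, cut)
            row["cutoff"] = cut
            ps = {}
            for endpoint in ("os", "dfs"):
                sub = cf.reindex(list(ptmb.sample_ids))
                ok = sub[f"{endpoint}_time"].notna() & sub[f"{endpoint}_event"].notna()
                labels = strat.as_series()[ok.to_numpy()]
                t = sub.loc[ok.to_numpy(), f"{endpoint}_time"].to_numpy(dtype=float)
                e = sub.loc[ok.to_numpy(), f"{endpoint}_event"].to_numpy(dtype=float)
                hi = (labels == "high").to_numpy()
                if hi.all() or not hi.any() or hi.size == 0:
                    ps[endpoint] = np.nan
                    continue
                _, p = logrank_test(t[hi], e[hi], t[~hi], e[~hi])
                ps[endpoint] = p
            row["os_logrank_p"] = ps["os"]
            row["dfs_logrank_p"] = ps["dfs"]
            if (np.isfinite(ps["os"]) and np.isfinite(ps["dfs"])
                    and ps["os"] < survival_alpha and ps["dfs"] < survival_alpha):
                row["eligible"] = True
                eligible.append((s.k, {"summary": s, "cutoff": cut, **ps}))
        diag_rows.append(row)
    diagnostics = pd.DataFrame(diag_rows)
    if not eligible:
        logger.warning("no panel size is eligible under r > %s and survival alpha %s",
                       r_threshold, survival_alpha)
        return FinalSelection(
            panel=None, k=None, r_train=None, cutoff=None,
            os_logrank_p=None, dfs_logrank_p=None,
            eligible_sizes=(), diagnostics=diagnostics,
        )
    eligible.sort(key=lambda e: e[0])
    k, info = eligible[0]
    s = info["summary"]
    final = Panel(genes=s.best_panel.genes, name=f"final_k{k}")
    return FinalSelection(
        panel=final, k=k, r_train=s.max_r, cutoff=info["cutoff"],
        os_logrank_p=info["os"], dfs_logrank_p=info["dfs"],
        eligible_sizes=tuple(e[0] for e in eligible), diagnostics=diagnostics,
    )


def empirical_pvalue_r(
    x: Sequence[float], y: Sequence[float], n_perm: int = 10000, seed: int = 0
) -> float:
    """Permutation empirical p-value for a Pearson correlation (two-sided).

    ``y`` is permuted over samples ``n_perm`` times;
    p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs = pearson_r(x, y)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(y) for _ in range(n_perm)])
    xc = x - x.mean()
    xn = np.linalg.norm(xc)
    pc = perms - perms.mean(axis=1, keepdims=True)
    pn = np.linalg.norm(pc, axis=1)
    r_perm = (pc @ xc) / (pn * xn)
    return float((1 + np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12)) / (n_perm + 1))


def search_table(summaries: Sequence[SizeSearchSummary]) -> pd.DataFrame:
    """Search results as a report DataFrame: k, mean r, max r, best panel genes."""
    return pd.DataFrame(
        [
            {"k": s.k, "n_reps": s.n_reps, "mean_r": s.mean_r, "max_r": s.max_r,
             "best_panel": ",".join(s.best_panel.genes)}
            for s in summaries
        ]
    )
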