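"""Per-sample TMB computation and high/low stratification.

TMB here is the raw count of nonsynonymous somatic mutations per sample:
the whole-exome value (WES-TMB) sums every gene, a panel estimate sums only
the panel's genes.  Samples are dichotomised at an integer cutoff, TMB-high
meaning value >= cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import MutationMatrix, Panel, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["TMBVector", "Stratification", "wes_tmb", "estimate_panel_tmb", "median_cutoff", "stratify"]


@dataclass(frozen=True)
class TMBVector:
    """Per-sample mutation-count totals, whole-exome or panel-restricted."""

    sample_ids: tuple[str, ...]
    values: np.ndarray  # int64, one per sample
    kind: Literal["wes", "panel"]
    source_panel: str = "ALL"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        v = np.asarray(self.values, dtype=np.int64)
        object.__setattr__(self, "values", v)
        if len(self.sample_ids) != v.shape[0]:
            raise ValidationError("one TMB value per sample required")
        if v.size and v.min() < 0:
            raise ValidationError("TMB values must be >= 0")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.sample_ids), name="tmb")

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class Stratification:
    """TMB-high/low labels at a cutoff (high iff value >= cutoff)."""

    cutoff: float
    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]  # 'high' | 'low' per sample

    @property
    def n_high(self) -> int:
        return sum(l == "high" for l in self.labels)

    @property
    def n_low(self) -> int:
        return sum(l == "low" for l in self.labels)

    def high_mask(self) -> np.ndarray:
        return np.array([l == "high" for l in self.labels])

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=list(self.sample_ids), name="label")


def wes_tmb(matrix: MutationMatrix) -> TMBVector:
    """Whole-exome TMB: per-sample sum of counts over all genes."""
    values = matrix.counts.to_numpy().sum(axis=0) if matrix.shape[0] else np.zeros(
        matrix.shape[1], dtype=np.int64
    )
    return TMBVector(sample_ids=tuple(matrix.samples), values=values, kind="wes", source_panel="ALL")


def estimate_panel_tmb(
    matrix: MutationMatrix, panel: Panel, allow_empty: bool = False
) -> TMBVector:
    """Panel-estimated TMB: per-sample sum of counts over the panel's genes.

    Panel genes absent from the matrix contribute 0 (with a warning); an
    empty panel is an error unless ``allow_empty`` is set, in which case the
    estimate is the zero vector.
    """
    if len(panel) == 0 and not allow_empty:
        raise ValidationError("empty panel; pass allow_empty=True for a zero estimate")
    present = [g for g in panel.genes if g in matrix.counts.index]
    absent = [g for g in panel.genes if g not in matrix.counts.index]
    if absent:
        logger.warning(
            "panel %r: %d/%d genes absent from matrix (contribute 0): %s",
            panel.name, len(absent), len(panel), absent[:10],
        )
    if present:
        values = matrix.counts.loc[present].to_numpy().sum(axis=0)
    else:
        values = np.zeros(matrix.shape[1], dtype=np.int64)
    return TMBVector(
        sample_ids=tuple(matrix.samples), values=values, kind="panel", source_panel=panel.name
    )


def median_cutoff(
    tmb: TMBVector, convention: Literal["lower", "interpolated"] = "lower"
) -> float:
    """Sample median of the TMB values, used as the high/low cutoff.

    The default "lower" convention returns, for even n, the lower of the two
    middle order statistics, so the cutoff is always an attained integer
    count; "interpolated" returns the usual midpoint median.
    """
    if len(tmb) == 0:
        raise ValidationError("median of an empty TMB vector is undefined")
    v = np.sort(tmb.values)
    n = v.shape[0]
    if convention == "lower":
        return float(v[(n - 1) // 2])
    if convention == "interpolated":
        return float(np.median(v))
    raise ValueError(f"unknown median convention {convention!r}")


def stratify(tmb: TMBVector, cutoff: float) -> Stratification:
    """Label each sample TMB-high (value >= cutoff) or TMB-low, preserving order."""
    if not np.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    labels = tuple("high" if v >= cutoff else "low" for v in tmb.values)
    return Stratification(cutoff=float(cutoff), sample_ids=tmb.sample_ids, labels=labels)
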