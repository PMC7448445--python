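"""Survival and response analyses for TMB stratifications.

Kaplan-Meier product-limit curves, the two-group log-rank test, univariable
Cox proportional-hazards ratios (TMB-high vs TMB-low), a hazard-ratio scan
over candidate cutoffs, and the Mann-Whitney comparison of estimated TMB
between immunotherapy response groups (DCB vs NDB).  Time is months
throughout; an event flag of 0 means right-censored at last follow-up.

The heavy lifting is delegated to lifelines (Efron tie handling for Cox, its
default); this module owns the stratification plumbing and result shapes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .io import ValidationError
from .tmb import Stratification, TMBVector, stratify
from .candidates import mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "CoxResult",
    "SurvivalComparison",
    "km_estimate",
    "logrank_test",
    "cox_hr",
    "compare_survival",
    "cutoff_scan",
    "compare_response_groups",
]


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier step function: survival probability and risk set per time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival, "at_risk": self.at_risk})

    def median_time(self) -> Optional[float]:
        """First time the curve reaches <= 0.5, or None if it never does."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else None


@dataclass(frozen=True)
class CoxResult:
    """Univariable Cox fit of the high-vs-low indicator (Wald 95% CI)."""

    hr: float
    ci_low: float
    ci_high: float
    p: float
    flagged: bool = False  # monotone likelihood / non-convergence: CI unbounded


@dataclass(frozen=True)
class SurvivalComparison:
    """Two-group (TMB-high vs TMB-low) survival comparison for one endpoint."""

    endpoint: str
    n_high: int
    n_low: int
    logrank_chi2: float
    logrank_p: float
    hr: float
    hr_ci_low: float
    hr_ci_high: float
    cox_p: float
    median_time_high: Optional[float]
    median_time_low: Optional[float]
    flagged: bool = False


def _check_surv(times: Sequence[float], events: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.shape != e.shape or t.ndim != 1:
        raise ValidationError("times and events must be equal-length 1-d vectors")
    if t.size == 0:
        raise ValidationError("empty survival input")
    if (t < 0).any():
        raise ValidationError("survival times must be >= 0")
    if not np.isin(e, (0.0, 1.0)).all():
        raise ValidationError("event flags must be 0/1")
    return t, e.astype(int)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Product-limit survival estimate; censoring shrinks the risk set only."""
    t, e = _check_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill().to_numpy()
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.to_numpy(dtype=float),
        at_risk=at_risk.astype(float),
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, two-sided p on 1 df)."""
    ta, ea = _check_surv(times_a, events_a)
    tb, eb = _check_surv(times_b, events_b)
    if ta.max() == 0 or tb.max() == 0:
        raise ValidationError("a group has zero observed time span")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def cox_hr(
    labels: Sequence[str],
    times: Sequence[float],
    events: Sequence[int],
) -> CoxResult:
    """Univariable Cox PH fit with TMB-high as the indicator covariate.

    Efron tie handling (lifelines default).  A monotone likelihood (all
    events in one group, perfect separation) or non-convergence is reported
    as a flagged result with an unbounded CI, not an exception.
    """
    t, e = _check_surv(times, events)
    lab = np.asarray(labels)
    if not set(np.unique(lab)) <= {"high", "low"}:
        raise ValidationError("labels must be 'high'/'low'")
    if (lab == "high").sum() == 0 or (lab == "low").sum() == 0:
        raise ValidationError("both label groups must be non-empty")
    if e.sum() == 0:
        raise ValidationError("no events observed; hazard ratio undefined")
    df = pd.DataFrame({"time": t, "event": e, "high": (lab == "high").astype(int)})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError) as exc:
        logger.warning("Cox fit failed (monotone likelihood?): %s", exc)
        return CoxResult(hr=np.nan, ci_low=0.0, ci_high=np.inf, p=np.nan, flagged=True)
    coef = float(cph.params_["high"])
    se = float(cph.standard_errors_["high"])
    p = float(cph.summary.loc["high", "p"])
    flagged = not np.isfinite(se) or se > 10  # effectively unbounded Wald CI
    return CoxResult(
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        p=p,
        flagged=flagged,
    )


def compare_survival(
    strat: Stratification,
    times: Sequence[float],
    events: Sequence[int],
    endpoint: str = "OS",
) -> SurvivalComparison:
    """Full high-vs-low comparison: log-rank, Cox HR and median survival times.

    ``times``/``events`` are aligned with ``strat.sample_ids``.
    """
    t, e = _check_surv(times, events)
    high = strat.high_mask()
    if high.all() or not high.any():
        raise ValidationError("stratification has an empty group")
    chi2, p = logrank_test(t[high], e[high], t[~high], e[~high])
    cox = cox_hr(list(strat.labels), t, e)
    km_hi = km_estimate(t[high], e[high])
    km_lo = km_estimate(t[~high], e[~high])
    return SurvivalComparison(
        endpoint=endpoint,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        logrank_chi2=chi2,
        logrank_p=p,
        hr=cox.hr,
        hr_ci_low=cox.ci_low,
        hr_ci_high=cox.ci_high,
        cox_p=cox.p,
        median_time_high=km_hi.median_time(),
        median_time_low=km_lo.median_time(),
        flagged=cox.flagged,
    )


def cutoff_scan(
    tmb: TMBVector,
    times: Sequence[float],
    events: Sequence[int],
    cutoffs: Sequence[float],
) -> pd.DataFrame:
    """Hazard ratio and log-rank p at each candidate cutoff.

    One row per cutoff; cutoffs that leave one stratum empty are reported as
    not-evaluable rows (NaN statistics, evaluable=False) rather than errors.
    """
    t, e = _check_surv(times, events)
    rows = []
    for c in cutoffs:
        strat = stratify(tmb, c)
        row: dict = {"cutoff": float(c), "n_high": strat.n_high, "n_low": strat.n_low}
        if strat.n_high == 0 or strat.n_low == 0:
            row.update(
                hr=np.nan, ci_low=np.nan, ci_high=np.nan, logrank_p=np.nan, evaluable=False
            )
        else:
            high = strat.high_mask()
            chi2, p = logrank_test(t[high], e[high], t[~high], e[~high])
            cox = cox_hr(list(strat.labels), t, e)
            row.update(
                hr=cox.hr, ci_low=cox.ci_low, ci_high=cox.ci_high,
                logrank_p=p, evaluable=not cox.flagged,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def compare_response_groups(
    tmb: TMBVector, responses: Sequence[Optional[str]]
) -> tuple[float, float, float, float]:
    """Mann-Whitney comparison of estimated TMB between DCB and NDB patients.

    ``responses`` aligns with ``tmb.sample_ids``; missing (None) responses
    are excluded.  Returns (U, two-sided p, median TMB in DCB, median in NDB).
    """
    resp = np.asarray([r if r is not None else "" for r in responses])
    if resp.shape[0] != len(tmb):
        raise ValidationError("one response label per sample required")
    dcb = tmb.values[resp == "DCB"].astype(float)
    ndb = tmb.values[resp == "NDB"].astype(float)
    if dcb.size == 0 or ndb.size == 0:
        raise ValidationError("both DCB and NDB groups must be non-empty")
    u, p = mann_whitney(dcb, ndb)
    return u, p, float(np.median(dcb)), float(np.median(ndb))
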