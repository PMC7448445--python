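"""Synthetic NSCLC-like cohorts with planted ground truth.

The generator emulates the statistical structure the panel-search pipeline
assumes, with truth labels for parameter-recovery testing:

* a heavy-tailed latent per-sample mutational burden
  ``lambda_i ~ LogNormal(burden_log_mean, burden_log_sd)``;
* *informative* genes whose per-sample mutation counts scale with that
  burden, ``counts[g, i] ~ Poisson(lambda_i * w_g)`` with gene weights
  ``w_g`` drawn uniformly from ``informative_weight_range``;
* burden-independent *noise* genes, ``counts[g, i] ~ Poisson(mu_g)`` with
  ``mu_g`` uniform from ``noise_rate_range``;
* right-censored exponential survival (OS, and DFS/PFS at higher baseline
  hazards) with hazard ``baseline * exp(beta * 1[WES-TMB_i >= median])`` —
  ``beta = hazard_log_hr`` plants a TMB-high-vs-low hazard ratio; an
  alternative continuous mode applies beta per standardized WES-TMB;
* a binary immunotherapy response label,
  ``P(DCB) = logistic(intercept + slope * standardized WES-TMB)``.

Censoring times are exponential with per-sample hazard
``h_i * censoring_rate / (1 - censoring_rate)``, which makes the expected
censored fraction exactly ``censoring_rate`` for exponential event times.
Everything is reproducible from ``SimParams.seed``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np

from .io import (
    NONSYNONYMOUS_CLASSES,
    ClinicalRecord,
    MutationMatrix,
    Panel,
    ValidationError,
    write_clinical,
)

__all__ = ["SimParams", "SimTruth", "simulate_cohort", "write_cohort"]

# DFS/PFS event rates exceed OS in the populations emulated here
_ENDPOINT_HAZARD_MULT = {"os": 1.0, "dfs": 1.5, "pfs": 2.0}


@dataclass(frozen=True)
class SimParams:
    """Generator configuration; defaults define the standard study conditions."""

    n_samples: int = 500
    n_genes: int = 2000
    n_informative: int = 150
    burden_log_mean: float = math.log(100.0)
    burden_log_sd: float = 0.8
    informative_weight_range: tuple[float, float] = (0.002, 0.006)
    noise_rate_range: tuple[float, float] = (0.0, 0.3)
    hazard_log_hr: float = math.log(0.5)
    baseline_hazard: float = 0.02  # events per month in the TMB-low OS group
    censoring_rate: float = 0.3
    response_logit_slope: float = 1.0
    response_logit_intercept: float = 0.0
    hazard_mode: Literal["threshold", "continuous"] = "threshold"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValidationError("n_samples and n_genes must be positive")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValidationError("need 0 <= n_informative <= n_genes")
        if self.burden_log_sd < 0 or self.baseline_hazard <= 0:
            raise ValidationError("burden_log_sd must be >= 0 and baseline_hazard > 0")
        for lo, hi in (self.informative_weight_range, self.noise_rate_range):
            if lo < 0 or hi < lo:
                raise ValidationError("rate/weight ranges must satisfy 0 <= lo <= hi")
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError("censoring_rate must be in [0, 1)")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated cohort, for parameter-recovery checks."""

    lam: np.ndarray  # latent burden per sample
    informative_genes: tuple[str, ...]
    weights: dict[str, float]  # informative w_g and noise mu_g, all genes
    high_labels: tuple[str, ...]  # realized WES-TMB >= median
    beta: float
    gamma: float

    def planted_panel(self, name: str = "planted") -> Panel:
        return Panel(genes=self.informative_genes, name=name)


def _gene_names(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"GENE{i:0{width}d}" for i in range(n)]


def simulate_cohort(
    params: SimParams,
) -> tuple[MutationMatrix, list[ClinicalRecord], SimTruth]:
    """Draw one cohort: mutation matrix, clinical records and ground truth."""
    import pandas as pd

    rng = np.random.default_rng(params.seed)
    n, g = params.n_samples, params.n_genes
    genes = _gene_names(g)
    samples = [f"S{i:04d}" for i in range(n)]

    lam = rng.lognormal(params.burden_log_mean, params.burden_log_sd, size=n)
    informative = tuple(genes[: params.n_informative])
    w_lo, w_hi = params.informative_weight_range
    m_lo, m_hi = params.noise_rate_range
    w = rng.uniform(w_lo, w_hi, size=params.n_informative)
    mu = rng.uniform(m_lo, m_hi, size=g - params.n_informative)

    counts = np.empty((g, n), dtype=np.int64)
    counts[: params.n_informative] = rng.poisson(np.outer(w, lam))
    counts[params.n_informative:] = rng.poisson(
        np.broadcast_to(mu[:, None], (g - params.n_informative, n))
    )
    matrix = MutationMatrix(counts=pd.DataFrame(counts, index=genes, columns=samples))

    wes = counts.sum(axis=0)
    med = float(np.sort(wes)[(n - 1) // 2])  # lower-median convention
    high = wes >= med

    if params.hazard_mode == "threshold":
        log_rel = params.hazard_log_hr * high.astype(float)
    else:
        z = (wes - wes.mean()) / wes.std() if wes.std() > 0 else np.zeros(n)
        log_rel = params.hazard_log_hr * z
    c = params.censoring_rate

    endpoint_data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for endpoint, mult in _ENDPOINT_HAZARD_MULT.items():
        h = params.baseline_hazard * mult * np.exp(log_rel)
        t_event = rng.exponential(1.0 / h)
        if c > 0:
            t_cens = rng.exponential((1.0 - c) / (c * h))
            time = np.minimum(t_event, t_cens)
            event = (t_event <= t_cens).astype(int)
        else:
            time, event = t_event, np.ones(n, dtype=int)
        endpoint_data[endpoint] = (time, event)

    z = (wes - wes.mean()) / wes.std() if wes.std() > 0 else np.zeros(n)
    p_dcb = 1.0 / (1.0 + np.exp(-(params.response_logit_intercept + params.response_logit_slope * z)))
    dcb = rng.random(n) < p_dcb
    histology = rng.choice(["LUAD", "LUSC"], size=n)
    stage = rng.choice(["I", "II", "III", "IV"], size=n)

    clinical = [
        ClinicalRecord(
            sample_id=samples[i],
            os_time=float(endpoint_data["os"][0][i]),
            os_event=int(endpoint_data["os"][1][i]),
            dfs_time=float(endpoint_data["dfs"][0][i]),
            dfs_event=int(endpoint_data["dfs"][1][i]),
            pfs_time=float(endpoint_data["pfs"][0][i]),
            pfs_event=int(endpoint_data["pfs"][1][i]),
            response="DCB" if dcb[i] else "NDB",
            histology=str(histology[i]),
            stage=str(stage[i]),
        )
        for i in range(n)
    ]

    weights = {g_: float(x) for g_, x in zip(genes[: params.n_informative], w)}
    weights.update({g_: float(x) for g_, x in zip(genes[params.n_informative:], mu)})
    truth = SimTruth(
        lam=lam,
        informative_genes=informative,
        weights=weights,
        high_labels=tuple("high" if h_ else "low" for h_ in high),
        beta=params.hazard_log_hr,
        gamma=params.response_logit_slope,
    )
    return matrix, clinical, truth


def write_cohort(
    matrix: MutationMatrix,
    clinical: Sequence[ClinicalRecord],
    truth: Optional[SimTruth],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write cohort.maf, clinical.tsv and (when truth is given) truth.json.

    The MAF emits one record per mutation count with fabricated coordinates
    (gene-index derived; downstream computation never reads them) and a
    classification cycled deterministically through the nonsynonymous
    vocabulary, so ``read_maf`` + ``build_mutation_matrix`` round-trips to
    the identical matrix.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    classes = sorted(NONSYNONYMOUS_CLASSES)
    maf_path = out / "cohort.maf"
    with maf_path.open("w") as fh:
        fh.write("#synthetic cohort\n")
        fh.write(
            "Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\t"
            "Tumor_Seq_Allele2\tVariant_Classification\tTumor_Sample_Barcode\n"
        )
        for gi, gene in enumerate(matrix.genes):
            row = matrix.counts.iloc[gi]
            for sample, count in row.items():
                for copy in range(int(count)):
                    vc = classes[(gi + copy) % len(classes)]
                    pos = gi * 1000 + copy + 1
                    fh.write(f"{gene}\t1\t{pos}\tA\tT\t{vc}\t{sample}\n")
    clin_path = out / "clinical.tsv"
    write_clinical(clinical, clin_path)
    paths = {"maf": maf_path, "clinical": clin_path}
    if truth is not None:
        truth_path = out / "truth.json"
        with truth_path.open("w") as fh:
            json.dump(
                {
                    "lambda": truth.lam.tolist(),
                    "informative_genes": list(truth.informative_genes),
                    "weights": truth.weights,
                    "high_labels": list(truth.high_labels),
                    "beta": truth.beta,
                    "gamma": truth.gamma,
                },
                fh,
                indent=1,
            )
        paths["truth"] = truth_path
    return paths
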