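"""End-to-end orchestration: construction and validation runs with manifests.

``run_construction`` executes the whole training path — MAF -> mutation
matrix -> WES-TMB -> candidate genes -> randomized size search -> survival-
filtered final panel — and writes every stage report plus a JSON manifest
(seeds, thresholds, input digests) sufficient to reproduce the run bit for
bit.  ``run_validation`` applies a fixed panel and training cutoff to a
validation cohort: correlation with WES-TMB plus permutation p, stratified
OS/DFS/PFS comparisons, the DCB-vs-NDB response comparison, and an optional
hazard-ratio cutoff scan.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    NONSYNONYMOUS_CLASSES,
    ClinicalRecord,
    MutationMatrix,
    Panel,
    ValidationError,
    build_mutation_matrix,
    clinical_frame,
    read_clinical,
    read_maf,
    write_panel,
    write_table,
)
from .tmb import TMBVector, estimate_panel_tmb, median_cutoff, stratify, wes_tmb
from .candidates import candidate_table, select_candidates
from .search import (
    FinalSelection,
    empirical_pvalue_r,
    pearson_r,
    search_by_size,
    search_table,
    select_final_panel,
)
from .survival import compare_response_groups, compare_survival, cutoff_scan

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConstructionResult", "run_construction", "run_validation"]


@dataclass
class RunConfig:
    """Flat configuration for a construction run (YAML-loadable)."""

    maf: str
    clinical: str
    out_dir: str
    nonsyn_classes: tuple[str, ...] = tuple(sorted(NONSYNONYMOUS_CLASSES))
    freq_min: float = 0.10
    alpha: float = 0.05
    adjust_method: str = "BH"
    require_positive: bool = True
    sizes: tuple[int, ...] = tuple(range(1, 31))
    n_reps: int = 1000
    r_threshold: float = 0.9
    survival_alpha: float = 0.05
    cutoff_convention: str = "lower"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.freq_min <= 1:
            raise ValidationError("freq_min must be in [0, 1]")
        for name in ("alpha", "survival_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1]")
        if not -1 <= self.r_threshold <= 1:
            raise ValidationError("r_threshold must be in [-1, 1]")
        if min(self.sizes, default=1) < 1 or self.n_reps < 1:
            raise ValidationError("sizes and n_reps must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        for key in ("nonsyn_classes", "sizes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass(frozen=True)
class ConstructionResult:
    """Everything a construction run produced, with output paths."""

    selection: FinalSelection
    candidates: list
    summaries: list
    wes: TMBVector
    matrix: MutationMatrix = field(repr=False)
    paths: dict[str, Path] = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    """Wrap stage execution so failures are surfaced with the stage name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_construction(config: RunConfig) -> ConstructionResult:
    """Run the full panel-construction pipeline and write stage reports."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("read"):
        records = read_maf(config.maf, nonsyn_classes=config.nonsyn_classes)
        clinical = read_clinical(config.clinical)
        cf = clinical_frame(clinical)
        for endpoint in ("os", "dfs"):
            if cf[f"{endpoint}_time"].isna().all():
                raise ValidationError(
                    f"training cohort lacks the {endpoint.upper()} endpoint entirely"
                )

    with _stage("matrix"):
        roster = [c.sample_id for c in clinical]
        matrix = build_mutation_matrix(records, samples=roster)
        logger.info("matrix: %d genes x %d samples, %d records",
                    *matrix.shape, matrix.total())

    with _stage("wes_tmb"):
        wes = wes_tmb(matrix)

    with _stage("candidates"):
        cands = select_candidates(
            matrix, wes,
            freq_min=config.freq_min, alpha=config.alpha,
            require_positive=config.require_positive,
            adjust_method=config.adjust_method,  # type: ignore[arg-type]
        )
        logger.info("candidates: %d genes pass frequency+association filters", len(cands))
        write_table(candidate_table(cands), out / "candidates.tsv")

    with _stage("search"):
        cand_genes = [c.gene_symbol for c in cands]
        sizes = tuple(k for k in config.sizes if k <= len(cand_genes))
        if sizes != tuple(config.sizes):
            logger.warning("sizes truncated to candidate pool size %d", len(cand_genes))
        if not sizes:
            raise ValidationError("candidate pool too small for any requested size")
        summaries = search_by_size(
            matrix, wes, cand_genes, sizes=sizes, n_reps=config.n_reps, seed=config.seed
        )
        write_table(search_table(summaries), out / "search_report.tsv")

    with _stage("final_selection"):
        selection = select_final_panel(
            summaries, matrix, clinical,
            r_threshold=config.r_threshold,
            survival_alpha=config.survival_alpha,
            cutoff_convention=config.cutoff_convention,
        )
        write_table(selection.diagnostics, out / "selection_diagnostics.tsv")
        paths = {
            "candidates": out / "candidates.tsv",
            "search_report": out / "search_report.tsv",
            "selection_diagnostics": out / "selection_diagnostics.tsv",
        }
        if selection.selected:
            panel_path = out / "final_panel.txt"
            write_panel(selection.panel, panel_path)
            paths["panel"] = panel_path
            ptmb = estimate_panel_tmb(matrix, selection.panel)
            strat = stratify(ptmb, selection.cutoff)
            tmb_tbl = pd.DataFrame(
                {
                    "sample_id": list(ptmb.sample_ids),
                    "tmb": ptmb.values,
                    "label": list(strat.labels),
                    "cutoff": selection.cutoff,
                    "panel_name": selection.panel.name,
                }
            )
            write_table(tmb_tbl, out / "panel_tmb.tsv")
            paths["panel_tmb"] = out / "panel_tmb.tsv"

    manifest = {
        "tool": "tmbpanel",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {
            "maf": {"path": str(config.maf), "sha256": _sha256(config.maf)},
            "clinical": {"path": str(config.clinical), "sha256": _sha256(config.clinical)},
        },
        "results": {
            "n_candidates": len(cands),
            "selected": selection.selected,
            "k": selection.k,
            "r_train": selection.r_train,
            "cutoff": selection.cutoff,
            "eligible_sizes": list(selection.eligible_sizes),
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths["manifest"] = manifest_path
    return ConstructionResult(
        selection=selection, candidates=cands, summaries=summaries,
        wes=wes, matrix=matrix, paths=paths,
    )


def run_validation(
    matrix: MutationMatrix,
    clinical: Sequence[ClinicalRecord],
    panel: Panel,
    cutoff: float,
    n_perm: int = 10000,
    seed: int = 0,
    scan_cutoffs: Optional[Sequence[float]] = None,
    out_dir: Optional[str | Path] = None,
) -> dict:
    """Validate a fixed panel (and training cutoff) on an independent cohort.

    Returns a nested report dict; endpoints or labels absent from the cohort
    are marked "not evaluated" and the remaining analyses proceed.  When
    ``out_dir`` is given the report is also written as JSON.
    """
    wes = wes_tmb(matrix)
    ptmb = estimate_panel_tmb(matrix, panel)
    r = pearson_r(ptmb.values.astype(float), wes.values.astype(float))
    p_emp = empirical_pvalue_r(
        ptmb.values.astype(float), wes.values.astype(float), n_perm=n_perm, seed=seed
    )
    strat = stratify(ptmb, cutoff)
    cf = clinical_frame(clinical).reindex(list(ptmb.sample_ids))

    report: dict = {
        "panel": panel.name,
        "n_samples": len(ptmb),
        "correlation": {"r": r, "empirical_p": p_emp, "n_perm": n_perm},
        "cutoff": float(cutoff),
        "n_high": strat.n_high,
        "n_low": strat.n_low,
        "survival": {},
    }

    for endpoint in ("os", "dfs", "pfs"):
        ok = (cf[f"{endpoint}_time"].notna() & cf[f"{endpoint}_event"].notna()).to_numpy()
        if ok.sum() == 0:
            report["survival"][endpoint.upper()] = "not evaluated"
            continue
        sub_labels = [l for l, k in zip(strat.labels, ok) if k]
        if len(set(sub_labels)) < 2:
            report["survival"][endpoint.upper()] = "not evaluated (one stratum empty)"
            continue
        sub_strat = stratify(
            TMBVector(
                sample_ids=tuple(s for s, k in zip(ptmb.sample_ids, ok) if k),
                values=ptmb.values[ok], kind="panel", source_panel=panel.name,
            ),
            cutoff,
        )
        comp = compare_survival(
            sub_strat,
            cf.loc[ok, f"{endpoint}_time"].to_numpy(dtype=float),
            cf.loc[ok, f"{endpoint}_event"].to_numpy(dtype=float),
            endpoint=endpoint.upper(),
        )
        report["survival"][endpoint.upper()] = {
            "n_high": comp.n_high, "n_low": comp.n_low,
            "logrank_chi2": comp.logrank_chi2, "logrank_p": comp.logrank_p,
            "hr": comp.hr, "hr_ci": [comp.hr_ci_low, comp.hr_ci_high],
            "median_time_high": comp.median_time_high,
            "median_time_low": comp.median_time_low,
        }

    responses = cf["response"].tolist()
    if any(r_ == "DCB" for r_ in responses) and any(r_ == "NDB" for r_ in responses):
        u, p, med_dcb, med_ndb = compare_response_groups(ptmb, responses)
        report["response"] = {
            "u_stat": u, "p": p, "median_tmb_dcb": med_dcb, "median_tmb_ndb": med_ndb,
            "n_dcb": sum(r_ == "DCB" for r_ in responses),
            "n_ndb": sum(r_ == "NDB" for r_ in responses),
        }
    else:
        report["response"] = "not evaluated"

    if scan_cutoffs is not None:
        ok = (cf["pfs_time"].notna() & cf["pfs_event"].notna()).to_numpy()
        if ok.sum():
            sub = TMBVector(
                sample_ids=tuple(s for s, k in zip(ptmb.sample_ids, ok) if k),
                values=ptmb.values[ok], kind="panel", source_panel=panel.name,
            )
            scan = cutoff_scan(
                sub,
                cf.loc[ok, "pfs_time"].to_numpy(dtype=float),
                cf.loc[ok, "pfs_event"].to_numpy(dtype=float),
                scan_cutoffs,
            )
            report["cutoff_scan"] = scan.to_dict(orient="records")
        else:
            report["cutoff_scan"] = "not evaluated"

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "validation_report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
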