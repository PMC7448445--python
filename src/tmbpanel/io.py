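"""Readers/writers for MAF-style mutation tables, clinical tables and gene panels.

The mutation substrate of the whole pipeline is a gene x sample matrix of
nonsynonymous somatic mutation *counts* built from TCGA-dialect MAF rows
(tab-separated, ``#`` comment lines, at least the columns ``Hugo_Symbol``,
``Tumor_Sample_Barcode`` and ``Variant_Classification``).  TMB is operated on
in raw counts throughout; no per-megabase normalisation is done here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NONSYNONYMOUS_CLASSES",
    "KNOWN_CLASSES",
    "MafFormatError",
    "ValidationError",
    "MutationRecord",
    "MutationMatrix",
    "ClinicalRecord",
    "Panel",
    "read_maf",
    "build_mutation_matrix",
    "read_clinical",
    "clinical_frame",
    "read_panel",
    "write_panel",
    "write_table",
    "write_clinical",
]

#: Default set of protein-altering MAF Variant_Classification terms.  TMB is
#: the count of these; everything else (Silent, UTR, intronic ...) is screened
#: out before the matrix is built.  Configurable at every call site.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Translation_Start_Site",
    }
)

#: Controlled vocabulary of Variant_Classification terms we recognise.  Terms
#: outside this set are flagged via logging, never silently dropped.
KNOWN_CLASSES = NONSYNONYMOUS_CLASSES | {
    "Silent",
    "3'UTR",
    "5'UTR",
    "3'Flank",
    "5'Flank",
    "Intron",
    "IGR",
    "RNA",
    "Targeted_Region",
    "De_novo_Start_InFrame",
    "De_novo_Start_OutOfFrame",
}


class MafFormatError(ValueError):
    """Raised when a MAF-like file violates the expected dialect."""


class ValidationError(ValueError):
    """Raised when a table's content violates a domain invariant."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call: a (sample, gene, classification) triple.

    Coordinates, when present, follow the MAF convention (1-based inclusive)
    but are never consumed by downstream computation.
    """

    sample_id: str
    gene_symbol: str
    variant_classification: str
    chrom: Optional[str] = None
    pos: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sample_id or not self.gene_symbol:
            raise ValidationError("sample_id and gene_symbol must be non-empty")


@dataclass(frozen=True)
class MutationMatrix:
    """Gene x sample grid of nonsynonymous mutation counts.

    ``counts`` is a pandas DataFrame with genes as the (lexicographically
    sorted, unique) index and samples as (unique) columns; every entry is a
    non-negative integer — the number of mutation records for that gene in
    that sample.  Samples with zero mutations are retained as all-zero
    columns.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValidationError("duplicate gene or sample identifiers")
        vals = c.to_numpy()
        if vals.size and (not np.issubdtype(vals.dtype, np.integer) or (vals < 0).any()):
            raise ValidationError("counts must be non-negative integers")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def total(self) -> int:
        """Grand total of mutation counts (conserves the record count)."""
        return int(self.counts.to_numpy().sum())


_RESPONSES = {"DCB", "NDB"}
_HISTOLOGIES = {"LUAD", "LUSC", "other"}


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-sample clinical annotations: survival endpoints and ICI response.

    Times are months; event flags are 1 = event observed, 0 = right-censored
    at last follow-up.  Any endpoint may be missing (``None``) and is simply
    excluded from analyses that need it.  ``response`` is DCB (durable
    clinical benefit: partial/stable disease lasting over 6 months on
    checkpoint inhibition) or NDB, or ``None`` when not assessed.
    """

    sample_id: str
    os_time: Optional[float] = None
    os_event: Optional[int] = None
    dfs_time: Optional[float] = None
    dfs_event: Optional[int] = None
    pfs_time: Optional[float] = None
    pfs_event: Optional[int] = None
    response: Optional[str] = None
    histology: str = "other"
    stage: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        for name in ("os", "dfs", "pfs"):
            t = getattr(self, f"{name}_time")
            e = getattr(self, f"{name}_event")
            if t is not None and t < 0:
                raise ValidationError(f"{self.sample_id}: {name}_time must be >= 0, got {t}")
            if e is not None and e not in (0, 1):
                raise ValidationError(f"{self.sample_id}: {name}_event must be 0/1, got {e}")
        if self.response is not None and self.response not in _RESPONSES:
            raise ValidationError(
                f"{self.sample_id}: response must be one of {sorted(_RESPONSES)} or missing, "
                f"got {self.response!r}"
            )
        if self.histology not in _HISTOLOGIES:
            raise ValidationError(
                f"{self.sample_id}: histology must be one of {sorted(_HISTOLOGIES)}"
            )


@dataclass(frozen=True)
class Panel:
    """An ordered gene panel, optionally annotated with per-gene CDS lengths."""

    genes: tuple[str, ...]
    cds_length: Optional[dict[str, int]] = None
    name: str = "panel"

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"panel {self.name!r} has duplicate gene symbols")
        if self.cds_length is not None:
            bad = {g: l for g, l in self.cds_length.items() if l <= 0}
            if bad:
                raise ValidationError(f"panel {self.name!r}: CDS lengths must be > 0: {bad}")

    def __len__(self) -> int:
        return len(self.genes)

    def total_cds_length(self) -> Optional[int]:
        if self.cds_length is None:
            return None
        if any(g not in self.cds_length for g in self.genes):
            return None
        return sum(self.cds_length[g] for g in self.genes)


_MAF_REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


def read_maf(
    path: str | Path,
    nonsyn_classes: Iterable[str] = NONSYNONYMOUS_CLASSES,
) -> list[MutationRecord]:
    """Read a MAF-like file and keep only nonsynonymous mutation records.

    Parameters
    ----------
    path
        Tab-separated file with a header containing at least Hugo_Symbol,
        Tumor_Sample_Barcode and Variant_Classification; lines starting with
        ``#`` are comments.
    nonsyn_classes
        The Variant_Classification terms counted as nonsynonymous.

    Returns
    -------
    Records whose classification is in ``nonsyn_classes``, in input order.
    Kept/dropped tallies are reported via logging; classifications outside
    the known vocabulary are flagged with a warning but handled like any
    other non-matching term.
    """
    nonsyn = frozenset(nonsyn_classes)
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise MafFormatError(f"{path}: missing required MAF column(s): {', '.join(missing)}")

    unknown = sorted(set(df["Variant_Classification"]) - KNOWN_CLASSES - nonsyn)
    if unknown:
        logger.warning("%s: unknown Variant_Classification terms flagged: %s", path, unknown)

    has_coords = all(c in df.columns for c in ("Chromosome", "Start_Position"))
    records: list[MutationRecord] = []
    for row in df.itertuples(index=False):
        vc = getattr(row, "Variant_Classification")
        if vc not in nonsyn:
            continue
        records.append(
            MutationRecord(
                sample_id=getattr(row, "Tumor_Sample_Barcode"),
                gene_symbol=getattr(row, "Hugo_Symbol").strip(),
                variant_classification=vc,
                chrom=getattr(row, "Chromosome") if has_coords else None,
                pos=int(getattr(row, "Start_Position")) if has_coords else None,
                ref=getattr(row, "Reference_Allele", None) if has_coords else None,
                alt=getattr(row, "Tumor_Seq_Allele2", None) if has_coords else None,
            )
        )
    logger.info(
        "%s: kept %d nonsynonymous records, dropped %d", path, len(records), len(df) - len(records)
    )
    if not records:
        logger.warning("%s: no records remain after the nonsynonymous screen", path)
    return records


def build_mutation_matrix(
    records: Sequence[MutationRecord],
    samples: Optional[Sequence[str]] = None,
    genes: Optional[Sequence[str]] = None,
) -> MutationMatrix:
    """Tally mutation records into a gene x sample count matrix.

    ``counts[g, s]`` is the number of records with gene ``g`` and sample
    ``s``; a gene hit twice in one sample contributes 2.  Genes are sorted
    lexicographically.  When an explicit sample roster is given, every
    record's sample must belong to it and roster samples without records
    become all-zero columns; otherwise samples appear in first-seen order.
    An explicit gene roster behaves analogously (all-zero rows retained).
    """
    if samples is not None:
        roster = list(samples)
        roster_set = set(roster)
        if len(roster_set) != len(roster):
            raise ValidationError("sample roster contains duplicates")
        outside = sorted({r.sample_id for r in records} - roster_set)
        if outside:
            raise ValidationError(f"records reference samples outside the roster: {outside}")
    else:
        seen: dict[str, None] = {}
        for r in records:
            seen.setdefault(r.sample_id, None)
        roster = list(seen)

    if genes is not None:
        gene_roster = sorted(set(genes))
        if len(gene_roster) != len(list(genes)):
            raise ValidationError("gene roster contains duplicates")
        outside = sorted({r.gene_symbol for r in records} - set(gene_roster))
        if outside:
            raise ValidationError(f"records reference genes outside the roster: {outside[:10]}")
        genes = gene_roster
    else:
        genes = sorted({r.gene_symbol for r in records})
    counts = pd.DataFrame(0, index=genes, columns=roster, dtype=np.int64)
    if records:
        tally = pd.DataFrame(
            {"gene": [r.gene_symbol for r in records], "sample": [r.sample_id for r in records]}
        )
        grouped = tally.groupby(["gene", "sample"]).size()
        for (g, s), n in grouped.items():
            counts.at[g, s] = n
    return MutationMatrix(counts=counts)


_CLINICAL_COLUMNS = (
    "sample_id",
    "os_time",
    "os_event",
    "dfs_time",
    "dfs_event",
    "pfs_time",
    "pfs_event",
    "response",
    "histology",
    "stage",
)


def _opt_float(v: str) -> Optional[float]:
    return None if v == "" else float(v)


def _opt_event(v: str) -> Optional[int]:
    if v == "":
        return None
    f = float(v)
    if f not in (0.0, 1.0):
        raise ValueError(f"event flag must be 0/1, got {v!r}")
    return int(f)


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical TSV (header per :data:`_CLINICAL_COLUMNS`; '' = missing).

    All offending rows are collected and reported together in a single
    :class:`ValidationError` so a malformed file can be fixed in one pass.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise MafFormatError(f"{path}: missing clinical column(s): {', '.join(missing)}")
    records: list[ClinicalRecord] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            records.append(
                ClinicalRecord(
                    sample_id=row.sample_id,
                    os_time=_opt_float(row.os_time),
                    os_event=_opt_event(row.os_event),
                    dfs_time=_opt_float(row.dfs_time),
                    dfs_event=_opt_event(row.dfs_event),
                    pfs_time=_opt_float(row.pfs_time),
                    pfs_event=_opt_event(row.pfs_event),
                    response=row.response or None,
                    histology=row.histology or "other",
                    stage=row.stage,
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"line {i}: {exc}")
    if problems:
        raise ValidationError(f"{path}: invalid clinical rows:\n  " + "\n  ".join(problems))
    return records


def clinical_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a DataFrame indexed by sample_id (NaN = missing)."""
    df = pd.DataFrame([{c: getattr(r, c) for c in _CLINICAL_COLUMNS} for r in records])
    return df.set_index("sample_id")


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    """Write clinical records in the canonical TSV dialect ('' = missing)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_CLINICAL_COLUMNS) + "\n")
        for r in records:
            vals = []
            for c in _CLINICAL_COLUMNS:
                v = getattr(r, c)
                if v is None:
                    vals.append("")
                elif isinstance(v, float):
                    vals.append(repr(v))  # shortest round-trip representation
                else:
                    vals.append(str(v))
            fh.write("\t".join(vals) + "\n")


def read_panel(path: str | Path, name: Optional[str] = None) -> Panel:
    """Read a panel file: one gene symbol per line, optional tab-separated CDS length."""
    path = Path(path)
    genes: list[str] = []
    cds: dict[str, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            gene = parts[0].strip()
            genes.append(gene)
            if len(parts) > 1 and parts[1].strip():
                length = int(parts[1])
                if length <= 0:
                    raise ValidationError(f"{path}: line {lineno}: CDS length must be > 0")
                cds[gene] = length
    return Panel(genes=tuple(genes), cds_length=cds or None, name=name or path.stem)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel file (round-trip stable with :func:`read_panel`)."""
    path = Path(path)
    with path.open("w") as fh:
        for g in panel.genes:
            if panel.cds_length and g in panel.cds_length:
                fh.write(f"{g}\t{panel.cds_length[g]}\n")
            else:
                fh.write(f"{g}\n")


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a report table as TSV (no index column)."""
    rows.to_csv(path, sep="\t", index=False)
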