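"""Data model and readers/writers for long-format precursor report tables.

The central in-memory container is :class:`ReportTable`, a thin wrapper around a
:class:`pandas.DataFrame` in a canonical long format: one row per identified
precursor per run, with linear-scale intensity, run-wise and global q-values on
precursor and protein-group level, a species label (``human`` / ``entrapment`` /
``shared`` / ``unknown``) and an identification provenance (``first_pass`` /
``matched`` / ``unknown``).

Readers accept DIA-NN-style report tables (``Run``, ``Protein.Group``,
``Modified.Sequence``, ``Precursor.Charge``, ``Precursor.Quantity``, ``Q.Value``,
``Lib.Q.Value``, ``PG.Q.Value``, ``Lib.PG.Q.Value``) or a generic dialect that
already uses the canonical column names. Intensities are stored linear in
records; protein matrices produced by :func:`pivot_protein_matrix` are log2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ReportFormatError",
    "SpeciesAssignmentError",
    "CANONICAL_COLUMNS",
    "DIANN_COLUMN_MAP",
    "SPECIES_LABELS",
    "PROVENANCE_LABELS",
    "ReportTable",
    "SpeciesMap",
    "read_report",
    "write_report",
    "read_annotations",
    "write_annotations",
    "read_species_map",
    "species_map_from_fasta",
    "assign_species",
    "pivot_protein_matrix",
]


class ReportFormatError(ValueError):
    """Raised when an input table violates the report-table contract."""


class SpeciesAssignmentError(ValueError):
    """Raised when protein identifiers cannot be mapped to a species."""


#: canonical column order of the long report format
CANONICAL_COLUMNS = [
    "run_id",
    "protein_group",
    "precursor_id",
    "intensity",
    "q_run",
    "q_global",
    "pgq_run",
    "pgq_global",
    "species",
    "provenance",
]

#: DIA-NN report header -> canonical column
DIANN_COLUMN_MAP = {
    "Run": "run_id",
    "Protein.Group": "protein_group",
    "Modified.Sequence": "modified_sequence",
    "Precursor.Charge": "precursor_charge",
    "Precursor.Quantity": "intensity",
    "Q.Value": "q_run",
    "Lib.Q.Value": "q_global",
    "PG.Q.Value": "pgq_run",
    "Lib.PG.Q.Value": "pgq_global",
}

DIANN_REQUIRED = ["Run", "Protein.Group", "Modified.Sequence", "Precursor.Charge", "Precursor.Quantity"]
GENERIC_REQUIRED = ["run_id", "protein_group", "precursor_id", "intensity"]

SPECIES_LABELS = ("human", "entrapment", "shared", "unknown")
PROVENANCE_LABELS = ("first_pass", "matched", "unknown")

_NUMERIC_COLUMNS = ["intensity", "q_run", "q_global", "pgq_run", "pgq_global"]


@dataclass
class ReportTable:
    """Long-format precursor report.

    Parameters
    ----------
    df:
        DataFrame with the canonical columns. ``(run_id, precursor_id)`` pairs
        must be unique; intensities are linear-scale and non-negative.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ReportFormatError(f"report table missing canonical columns: {missing}")
        self.df = self.df[CANONICAL_COLUMNS].reset_index(drop=True)
        _validate_records(self.df)

    @property
    def runs(self) -> list[str]:
        """Run identifiers in first-appearance order."""
        return list(dict.fromkeys(self.df["run_id"]))

    def __len__(self) -> int:
        return len(self.df)

    def subset_runs(self, runs: Iterable[str]) -> "ReportTable":
        keep = set(runs)
        return ReportTable(self.df[self.df["run_id"].isin(keep)].copy())


def _validate_records(df: pd.DataFrame) -> None:
    if len(df) == 0:
        return
    dup = df.duplicated(subset=["run_id", "precursor_id"])
    if dup.any():
        keys = df.loc[dup, ["run_id", "precursor_id"]].apply(tuple, axis=1).tolist()
        raise ReportFormatError(f"duplicate (run, precursor) rows: {keys[:10]}")
    intens = df["intensity"].to_numpy(dtype=float)
    if np.any(intens[~np.isnan(intens)] < 0):
        raise ReportFormatError("negative intensities in report table")
    for col in ["q_run", "q_global", "pgq_run", "pgq_global"]:
        vals = df[col].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ReportFormatError(f"{col} outside [0, 1]")


@dataclass
class SpeciesMap:
    """Protein identifier -> species label, plus peptides shared between proteomes.

    ``mapping`` values must be ``human`` or ``entrapment``; peptide sequences in
    ``shared_peptides`` force the ``shared`` label regardless of the protein group.
    """

    mapping: dict[str, str]
    shared_peptides: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = {v for v in self.mapping.values()} - {"human", "entrapment"}
        if bad:
            raise SpeciesAssignmentError(f"species map labels must be human/entrapment, got {sorted(bad)}")


def _coerce_numeric(df: pd.DataFrame, columns: list[str], path: str) -> pd.DataFrame:
    for col in columns:
        if col not in df.columns:
            continue
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ReportFormatError(f"{path}: unparsable numeric in column {col!r} at line {line}")
        df[col] = coerced
    return df


def read_report(path: str | Path, dialect: str = "diann", column_map: Mapping[str, str] | None = None) -> ReportTable:
    """Read a tab-separated precursor report table.

    ``dialect="diann"`` expects DIA-NN headers; ``dialect="generic"`` expects
    canonical headers. ``column_map`` renames input headers before dialect
    handling, so other spellings can be accommodated.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    if dialect == "diann":
        required = DIANN_REQUIRED
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ReportFormatError(f"{path}: missing required column(s) {missing}")
        df = df.rename(columns=DIANN_COLUMN_MAP)
        df["precursor_id"] = df["modified_sequence"].astype(str) + "/" + df["precursor_charge"].astype(str)
        df = df.drop(columns=["modified_sequence", "precursor_charge"])
    elif dialect == "generic":
        missing = [c for c in GENERIC_REQUIRED if c not in df.columns]
        if missing:
            raise ReportFormatError(f"{path}: missing required column(s) {missing}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for col, default in [
        ("q_run", np.nan),
        ("q_global", np.nan),
        ("pgq_run", np.nan),
        ("pgq_global", np.nan),
        ("species", "unknown"),
        ("provenance", "unknown"),
    ]:
        if col not in df.columns:
            df[col] = default
    df["species"] = df["species"].fillna("unknown")
    df["provenance"] = df["provenance"].fillna("unknown")
    df = _coerce_numeric(df, _NUMERIC_COLUMNS, str(path))
    return ReportTable(df)


def write_report(table: ReportTable, path: str | Path) -> None:
    """Write the canonical tab-separated report; missing values become empty fields."""
    table.df.to_csv(path, sep="\t", index=False, na_rep="")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table (run_id, role, condition, replicate)."""
    ann = pd.read_csv(path, sep="\t", dtype={"run_id": str, "role": str, "condition": str})
    required = ["run_id", "role", "condition", "replicate"]
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise ReportFormatError(f"{path}: annotation missing column(s) {missing}")
    return validate_annotations(ann)


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    if ann["run_id"].duplicated().any():
        dups = ann.loc[ann["run_id"].duplicated(), "run_id"].tolist()
        raise ReportFormatError(f"duplicate run_id in annotation: {dups}")
    bad_roles = set(ann["role"]) - {"analyte", "me", "blank"}
    if bad_roles:
        raise ReportFormatError(f"unknown roles in annotation: {sorted(bad_roles)}")
    ann = ann.copy()
    ann["replicate"] = ann["replicate"].astype(int)
    if (ann["replicate"] < 1).any():
        raise ReportFormatError("replicate numbers must be >= 1")
    return ann


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_species_map(path: str | Path) -> SpeciesMap:
    """Read a two-column (identifier <tab> species) mapping file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["protein", "species"], dtype=str)
    return SpeciesMap(mapping=dict(zip(df["protein"], df["species"])))


_TRYPTIC = re.compile(r".*?[KR](?!P)|.+$")


def tryptic_peptides(sequence: str, min_length: int = 7) -> set[str]:
    """Fully tryptic peptides (cut after K/R, not before P) of at least ``min_length``."""
    peptides = _TRYPTIC.findall(sequence.upper())
    return {p for p in peptides if len(p) >= min_length}


def species_map_from_fasta(
    fasta_paths: Mapping[str, str | Path],
    detect_shared_peptides: bool = True,
    min_peptide_length: int = 7,
) -> SpeciesMap:
    """Build a species map from FASTA files, one per species label.

    ``fasta_paths`` maps the species label (``human`` / ``entrapment``) to a FASTA
    file. Identifiers are taken from the accession field of UniProt-style headers
    (``>db|ACCESSION|NAME``) or the first whitespace-delimited token otherwise.
    When ``detect_shared_peptides`` is set, tryptic peptides derivable from both
    proteomes are collected into ``shared_peptides``.
    """
    mapping: dict[str, str] = {}
    peptide_sets: dict[str, set[str]] = {}
    for label, fp in fasta_paths.items():
        peptides: set[str] = set()
        for header, seq in _iter_fasta(Path(fp)):
            acc = _accession_from_header(header)
            mapping[acc] = label
            if detect_shared_peptides:
                peptides |= tryptic_peptides(seq, min_peptide_length)
        peptide_sets[label] = peptides
    shared: set[str] = set()
    if detect_shared_peptides and len(peptide_sets) == 2:
        a, b = peptide_sets.values()
        shared = a & b
    return SpeciesMap(mapping=mapping, shared_peptides=shared)


def _iter_fasta(path: Path):
    header, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if header is not None:
        yield header, "".join(chunks)


def _accession_from_header(header: str) -> str:
    token = header.split()[0]
    parts = token.split("|")
    return parts[1] if len(parts) >= 3 else token


def _strip_modifications(precursor_id: str) -> str:
    """Bare peptide sequence from a precursor id (drop charge suffix and mods)."""
    seq = precursor_id.rsplit("/", 1)[0]
    return re.sub(r"\(.*?\)|\[.*?\]", "", seq)


def assign_species(table: ReportTable, smap: SpeciesMap, default: str | None = None) -> ReportTable:
    """Label each record human/entrapment/shared from its protein group.

    Protein groups mixing species, and records whose (modification-stripped)
    peptide sequence occurs in both proteomes, are labelled ``shared``; shared
    records are excluded from species-specific metrics downstream. Idempotent:
    a record already labelled ``shared`` stays shared.
    """
    df = table.df.copy()
    groups = df["protein_group"].astype(str)
    unique_groups = groups.unique()
    labels: dict[str, str] = {}
    unmapped: set[str] = set()
    for grp in unique_groups:
        members = [m for m in grp.split(";") if m]
        member_labels = set()
        for m in members:
            lab = smap.mapping.get(m)
            if lab is None:
                if default is None:
                    unmapped.add(m)
                    continue
                lab = default
            member_labels.add(lab)
        labels[grp] = "shared" if len(member_labels) > 1 else next(iter(member_labels), "unknown")
    if unmapped:
        raise SpeciesAssignmentError(f"unmapped protein identifiers without default: {sorted(unmapped)[:10]}")
    new_species = groups.map(labels)
    if smap.shared_peptides:
        peptides = df["precursor_id"].map(_strip_modifications)
        new_species = new_species.mask(peptides.isin(smap.shared_peptides), "shared")
    # never relabel shared -> non-shared
    new_species = new_species.mask(df["species"] == "shared", "shared")
    df["species"] = new_species
    return ReportTable(df)


def pivot_protein_matrix(
    table: ReportTable,
    annotations: pd.DataFrame | None = None,
    aggregation: str = "median",
) -> pd.DataFrame:
    """Pivot a report into a log2 protein-group x run matrix.

    With ``aggregation="median"`` a protein's value per run is the median of its
    ions' log2 intensities; with ``"sum"`` it is the log2 of the summed linear
    intensity. When ``annotations`` are given, only analyte runs form columns.
    """
    df = table.df
    if annotations is not None:
        analyte_runs = annotations.loc[annotations["role"] == "analyte", "run_id"]
        df = df[df["run_id"].isin(set(analyte_runs))]
        columns = [r for r in analyte_runs if r in set(df["run_id"])]
    else:
        columns = list(dict.fromkeys(df["run_id"]))
    if not columns:
        raise ReportFormatError("no analyte runs to pivot")
    work = df[df["intensity"] > 0].copy()
    if aggregation == "median":
        work["log2"] = np.log2(work["intensity"])
        mat = work.pivot_table(index="protein_group", columns="run_id", values="log2", aggfunc="median")
    elif aggregation == "sum":
        mat = work.pivot_table(index="protein_group", columns="run_id", values="intensity", aggfunc="sum")
        mat = np.log2(mat)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    mat = mat.reindex(columns=columns)
    mat.index.name = "protein_group"
    mat.columns.name = "run_id"
    return mat


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a protein matrix (first column protein group, remaining columns runs)."""
    matrix.to_csv(path, sep="\t", na_rep="")


def read_matrix(path: str | Path) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index.name = "protein_group"
    mat.columns.name = "run_id"
    return mat
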