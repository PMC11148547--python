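"""Readers and writers for the tabular artifacts every pipeline stage exchanges.

All stages compose through plain files: beta matrices and delta-beta tables
as TSV, sample sheets and score tables as CSV, CpG sets as two-column TSV.
Dialect is fixed (UTF-8, '.' decimal, no thousands separators); beta values
are written with six decimals, missing values as ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "SampleSheet",
    "CpGSet",
    "FormatError",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_cpg_sets",
    "write_cpg_sets",
    "read_annotation",
]

NA_TOKEN = "NA"
BETA_DECIMALS = 6

SMOKING_TYPES = ("never", "ex", "current", "ecig", "smokeless", "nonsmoker")
DURATION_CATEGORIES = ("<=1y", "1-5y", ">5y", "NA")

SHEET_COLUMNS = [
    "sample_id",
    "tissue",
    "smoking_type",
    "age",
    "pack_years",
    "duration_category",
    "sex",
]


class FormatError(ValueError):
    """A file violates the declared dialect or an invariant of its type."""


@dataclass
class BetaMatrix:
    """CpG x sample matrix of methylation beta values in [0, 1].

    ``data`` is indexed by CpG identifier with one column per sample;
    missing measurements are NaN.  ``annotation`` optionally maps CpG id to
    a chromosome label and enables sex-chromosome filtering downstream.
    """

    data: pd.DataFrame
    annotation: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicated CpG ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicated sample ids: {dups[:5]}")
        values = self.data.to_numpy(dtype=float)
        bad = (values < 0) | (values > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"beta value out of [0,1] at CpG {idx[i]!r}, "
                f"sample {self.data.columns[j]!r}: {values[i, j]}"
            )

    @property
    def cpg_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())


@dataclass
class SampleSheet:
    """Per-sample phenotype records (tissue, smoking status, age, dose).

    One row per sample; ``smoking_type`` is drawn from the study vocabulary
    (never / ex / current plus the alternative-exposure labels).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SHEET_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        if self.data["sample_id"].duplicated().any():
            raise FormatError("duplicated sample_id in sample sheet")
        bad_types = set(self.data["smoking_type"]) - set(SMOKING_TYPES)
        if bad_types:
            raise FormatError(f"unknown smoking_type values: {sorted(bad_types)}")
        self.data = self.data.reset_index(drop=True)

    def for_samples(self, sample_ids) -> "SampleSheet":
        """Subset to the given samples, preserving their order."""
        sub = self.data.set_index("sample_id").reindex(sample_ids)
        if sub.isna().all(axis=1).any():
            lost = sub.index[sub.isna().all(axis=1)].tolist()
            raise FormatError(f"samples without sheet record: {lost[:5]}")
        return SampleSheet(sub.reset_index())

    def column(self, name: str, sample_ids) -> pd.Series:
        return self.data.set_index("sample_id")[name].reindex(sample_ids)


@dataclass
class CpGSet:
    """A named signature set of CpGs with the compartment its effect lives in.

    ``target_compartment`` decides which pure-compartment intercept the
    scoring correction extrapolates to: ``epithelial`` targets immune-cell
    proportion 0, ``immune`` targets proportion 1.
    """

    name: str
    cpgs: tuple[str, ...]
    target_compartment: str = "epithelial"

    def __post_init__(self) -> None:
        if not self.cpgs:
            raise FormatError(f"CpG set {self.name!r} is empty")
        if len(set(self.cpgs)) != len(self.cpgs):
            raise FormatError(f"CpG set {self.name!r} has duplicate members")
        if self.target_compartment not in ("epithelial", "immune"):
            raise FormatError(
                f"target_compartment must be 'epithelial' or 'immune', "
                f"got {self.target_compartment!r}"
            )

    @property
    def target_fraction(self) -> float:
        """Immune-cell proportion of the pure target compartment (0 or 1)."""
        return 1.0 if self.target_compartment == "immune" else 0.0


def default_compartment(set_name: str) -> str:
    """Sets whose name mentions 'immune' target the immune compartment."""
    return "immune" if "immune" in set_name.lower() else "epithelial"


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    out = beta.data.copy()
    out.insert(0, "cpg_id", out.index)
    out.to_csv(
        path,
        sep="\t",
        index=False,
        float_format=f"%.{BETA_DECIMALS}f",
        na_rep=NA_TOKEN,
    )


def read_beta_matrix(path, annotation: pd.Series | None = None) -> BetaMatrix:
    raw = pd.read_csv(path, sep="\t", dtype={"cpg_id": str}, na_values=[NA_TOKEN])
    if "cpg_id" not in raw.columns:
        raise FormatError(f"{path}: first column must be 'cpg_id'")
    raw = raw.set_index("cpg_id")
    for col in raw.columns:
        if not pd.api.types.is_numeric_dtype(raw[col]):
            bad = raw[col][pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()]
            raise FormatError(
                f"{path}: non-numeric beta in sample {col!r}"
                + (f" at CpG {bad.index[0]!r}: {bad.iloc[0]!r}" if len(bad) else "")
            )
    return BetaMatrix(raw.astype(float), annotation=annotation)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, index=False, na_rep=NA_TOKEN)


def read_sample_sheet(path) -> SampleSheet:
    raw = pd.read_csv(
        path,
        dtype={"sample_id": str, "tissue": str, "smoking_type": str, "sex": str},
        keep_default_na=False,
        na_values=[""],
    )
    if "duration_category" in raw.columns:
        raw["duration_category"] = raw["duration_category"].fillna("NA")
    for col in ("age", "pack_years"):
        if col in raw.columns:
            raw[col] = pd.to_numeric(raw[col].replace(NA_TOKEN, np.nan))
    return SampleSheet(raw)


def write_cpg_sets(sets: list[CpGSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write(f"# target_compartment: {s.name}={s.target_compartment}\n")
        fh.write("set_name\tcpg_id\n")
        for s in sets:
            for cpg in s.cpgs:
                fh.write(f"{s.name}\t{cpg}\n")


def read_cpg_sets(path) -> list[CpGSet]:
    """Parse a two-column (set_name, cpg_id) file into CpG sets.

    Comment lines ``# target_compartment: NAME=immune`` override the default
    name-based compartment assignment.
    """
    compartments: dict[str, str] = {}
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("target_compartment:"):
                    spec_ = body.split(":", 1)[1].strip()
                    name, _, comp = spec_.partition("=")
                    compartments[name.strip()] = comp.strip()
                continue
            parts = line.split("\t")
            if parts[:2] == ["set_name", "cpg_id"]:
                continue
            if len(parts) < 2:
                raise FormatError(f"{path}: expected two tab-separated columns: {line!r}")
            rows.append((parts[0], parts[1]))
    if not rows:
        raise FormatError(f"{path}: no CpG set rows found")
    seen = set()
    members: dict[str, list[str]] = {}
    for name, cpg in rows:
        if (name, cpg) in seen:
            raise FormatError(f"{path}: duplicate entry ({name!r}, {cpg!r})")
        seen.add((name, cpg))
        members.setdefault(name, []).append(cpg)
    return [
        CpGSet(
            name=name,
            cpgs=tuple(cpgs),
            target_compartment=compartments.get(name, default_compartment(name)),
        )
        for name, cpgs in members.items()
    ]


def read_annotation(path) -> pd.Series:
    """Read a (cpg_id, chromosome) TSV into a CpG -> chromosome mapping."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if list(raw.columns[:2]) != ["cpg_id", "chromosome"]:
        raise FormatError(f"{path}: expected columns cpg_id, chromosome")
    if raw["cpg_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated cpg_id in annotation")
    return raw.set_index("cpg_id")["chromosome"]
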