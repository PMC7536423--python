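"""Readers/writers for the pipeline's file formats and its in-memory containers.

All tabular formats are tab-separated text. Intensities on disk are raw
(linear scale); in memory everything is log2. Missing values are absent
rows in long tables and empty cells / NaN in wide profile tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "POOLS",
    "QuantMatrix",
    "ProfileMatrix",
    "AnnotationCatalog",
    "ComplexCatalog",
    "load_design",
    "write_design",
    "load_feature_table",
    "write_feature_table",
    "load_fasta",
    "load_annotations",
    "load_complexes",
    "load_profiles",
    "write_profiles",
    "median_normalize",
]

POOLS = ("surface", "total")

DESIGN_COLUMNS = ["sample_id", "pool", "condition", "replicate", "time_value"]
FEATURE_COLUMNS = ["feature_id", "protein_group", "sample_id", "intensity"]


def _validate_design(design: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DESIGN_COLUMNS[:4] if c not in design.columns]
    if missing:
        raise ValueError(f"design is missing required columns: {missing}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in design: {dup!r}")
    bad_pool = set(design["pool"]) - set(POOLS)
    if bad_pool:
        raise ValueError(f"unknown pool value(s) {sorted(bad_pool)}; expected one of {POOLS}")
    if (design["replicate"].astype(int) < 1).any():
        raise ValueError("replicate numbers must be positive integers")
    if "time_value" not in design.columns:
        design = design.assign(time_value=np.nan)
    return design.reset_index(drop=True)


def load_design(path: str | Path) -> pd.DataFrame:
    """Load a sample-design table (sample_id, pool, condition, replicate[, time_value])."""
    design = pd.read_csv(path, sep="\t")
    return _validate_design(design)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    _validate_design(design).to_csv(path, sep="\t", index=False)


@dataclass
class QuantMatrix:
    """Long-format log2 feature-intensity table with its sample design.

    ``data`` has columns (feature_id, protein_group, sample_id, log2_intensity);
    one row per observed (feature, sample). ``design`` maps each sample_id to
    pool / condition / replicate / time_value.
    """

    data: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.design = _validate_design(self.design)
        known = set(self.design["sample_id"])
        unknown = set(self.data["sample_id"]) - known
        if unknown:
            raise ValueError(f"sample_id {sorted(unknown)[0]!r} not present in the design")
        if self.data.duplicated(["feature_id", "sample_id"]).any():
            row = self.data[self.data.duplicated(["feature_id", "sample_id"])].iloc[0]
            raise ValueError(
                f"duplicate (feature_id, sample_id) observation: "
                f"({row['feature_id']!r}, {row['sample_id']!r})"
            )

    def subset_pool(self, pool: str) -> "QuantMatrix":
        keep = self.design[self.design["pool"] == pool]
        data = self.data[self.data["sample_id"].isin(set(keep["sample_id"]))]
        return QuantMatrix(data.reset_index(drop=True), keep.reset_index(drop=True))

    def annotated(self) -> pd.DataFrame:
        """Long table joined with the design columns."""
        return self.data.merge(self.design, on="sample_id", validate="many_to_one")


@dataclass
class ProfileMatrix:
    """Protein-group x time-point log2 abundance matrix for one pool.

    ``values``: DataFrame indexed by protein_group with one column per time
    point (numeric, strictly increasing); NaN marks a missing observation.
    """

    values: pd.DataFrame
    pool: str

    def __post_init__(self) -> None:
        cols = np.asarray(self.values.columns, dtype=float)
        if len(cols) > 1 and not np.all(np.diff(cols) > 0):
            raise ValueError("profile time points must be strictly increasing")
        self.values = self.values.copy()
        self.values.columns = cols
        if self.pool not in POOLS:
            raise ValueError(f"pool must be one of {POOLS}, got {self.pool!r}")

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)


@dataclass
class AnnotationCatalog:
    """Flat annotation sets: term_id -> (term_name, member accessions)."""

    terms: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, members in self.terms.items():
            if not members:
                raise ValueError(f"annotation term {tid!r} has no members")


@dataclass
class ComplexCatalog:
    """Protein-complex catalog: complex_id -> member accessions (>= 2)."""

    complexes: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, members in self.complexes.items():
            if len(members) < 2:
                raise ValueError(f"complex {cid!r} has fewer than 2 members")


def load_feature_table(path: str | Path, design_path: str | Path) -> QuantMatrix:
    """Load a raw feature-intensity table and log2-transform it.

    The file must have columns feature_id, protein_group, sample_id, intensity.
    Raw intensities that are zero, negative, or empty are treated as missing
    and dropped. Every sample_id must resolve in the design.
    """
    design = load_design(design_path)
    table = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "protein_group": str, "sample_id": str})
    missing_cols = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"feature table is missing columns: {missing_cols}")
    intensity = pd.to_numeric(table["intensity"], errors="coerce")
    bad = intensity.isna() & table["intensity"].notna() & (table["intensity"].astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"non-numeric intensity {table['intensity'].iloc[row]!r} at data row {row + 1}")
    keep = intensity.notna() & (intensity > 0)
    data = table.loc[keep, ["feature_id", "protein_group", "sample_id"]].copy()
    data["log2_intensity"] = np.log2(intensity[keep].to_numpy(dtype=float))
    return QuantMatrix(data.reset_index(drop=True), design)


def write_feature_table(matrix: QuantMatrix, path: str | Path) -> None:
    """Write a QuantMatrix back to disk on the raw (linear) intensity scale."""
    out = matrix.data[["feature_id", "protein_group", "sample_id"]].copy()
    out["intensity"] = np.exp2(matrix.data["log2_intensity"].to_numpy(dtype=float))
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|")


def load_fasta(path: str | Path, uniprot_dialect: bool = False) -> dict[str, str]:
    """Load protein sequences keyed by accession.

    The accession is the first whitespace-delimited header token; with
    ``uniprot_dialect`` the middle field of ``sp|ACC|NAME`` headers is used.
    Sequences are uppercased; duplicate accessions are an error.
    """
    sequences: dict[str, str] = {}
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    for rec in records:
        acc = rec.id
        if uniprot_dialect:
            m = _UNIPROT_HEADER.match(rec.id)
            if m:
                acc = m.group(1)
        if acc in sequences:
            raise ValueError(f"duplicate accession {acc!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for accession {acc!r}")
        sequences[acc] = seq
    return sequences


def _load_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has {len(fields)} fields, expected >= 3")
            set_id, name, *members = fields
            if set_id in sets:
                raise ValueError(f"{path}: duplicate id {set_id!r} at line {lineno}")
            sets[set_id] = {m for m in members if m}
            names[set_id] = name
    return sets, names


def load_annotations(path: str | Path) -> AnnotationCatalog:
    """Load a GMT-like annotation file (term_id, term_name, members...)."""
    sets, names = _load_gmt(path)
    return AnnotationCatalog(sets, names)


def load_complexes(path: str | Path) -> ComplexCatalog:
    """Load a GMT-like complex catalog (complex_id, name, >= 2 members)."""
    sets, names = _load_gmt(path)
    return ComplexCatalog(sets, names)


def write_profiles(profiles: ProfileMatrix, path: str | Path) -> None:
    out = profiles.values.copy()
    out.columns = [f"{c:g}" for c in profiles.timepoints]
    out.insert(0, "protein_group", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_profiles(path: str | Path, pool: str) -> ProfileMatrix:
    table = pd.read_csv(path, sep="\t")
    table = table.set_index("protein_group")
    table.columns = [float(c) for c in table.columns]
    return ProfileMatrix(table, pool)


def median_normalize(matrix: QuantMatrix) -> QuantMatrix:
    """Subtract each sample's median log2 intensity (optional, off by default
    in the pipeline because peptide amounts are assumed normalized upstream)."""
    data = matrix.data.copy()
    med = data.groupby("sample_id")["log2_intensity"].transform("median")
    data["log2_intensity"] = data["log2_intensity"] - med
    return QuantMatrix(data, matrix.design)
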