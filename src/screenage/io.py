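"""Readers and writers for the tab-separated interchange tables.

All tables are TSV with headered columns; missing values are written as
``NA``.  Readers validate the schema and raise :class:`SchemaError` naming
the offending column or value.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from screenage.trees import SpeciesTree

__all__ = [
    "SchemaError",
    "read_tsv",
    "write_tsv",
    "read_screen_table",
    "read_presence_matrix",
    "read_qpcr_table",
    "read_pool_table",
    "read_ages_table",
    "read_tree",
]

SCREEN_COLUMNS = [
    "line_id",
    "gene_id",
    "library",
    "has_30B3",
    "has_40D3",
    "recombined",
    "driver",
    "gfp_count",
    "nongfp_count",
    "phenotype",
]
QPCR_COLUMNS = ["sample_id", "line_id", "gene_id", "gene_role", "condition", "replicate", "ct"]


class SchemaError(ValueError):
    """An input table violates its column/value contract."""


def read_tsv(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", na_values=["NA", ""], keep_default_na=False, dtype=None
    )
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def read_screen_table(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, required=[c for c in SCREEN_COLUMNS if c != "phenotype"])
    for col in ("gfp_count", "nongfp_count"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype("Int64")
        if (df[col].dropna() < 0).any():
            raise SchemaError(f"{path}: negative values in column {col!r}")
    if "phenotype" in df.columns:
        bad = set(df["phenotype"].dropna()) - {
            "lethal",
            "semi-lethal",
            "non-lethal",
            "invalid",
            "uncalled",
        }
        if bad:
            raise SchemaError(f"{path}: invalid phenotype value(s) {sorted(bad)}")
    return df


def read_presence_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x species matrix with values in {1, 0, NA}; indexed by gene_id."""
    df = read_tsv(path, required=["gene_id"])
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise SchemaError(f"{path}: duplicate gene ids {dups[:5]}")
    df = df.set_index("gene_id")
    for col in df.columns:
        vals = set(df[col].dropna().unique())
        if not vals <= {0, 1, 0.0, 1.0, "0", "1"}:
            bad = sorted(v for v in vals if v not in {0, 1, 0.0, 1.0, "0", "1"})
            raise SchemaError(
                f"{path}: column {col!r} has value(s) {bad[:5]} outside {{1,0,NA}}"
            )
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, required=[c for c in QPCR_COLUMNS if c != "sample_id"])
    df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    if (df["ct"] <= 0).any():
        raise SchemaError(f"{path}: Ct values must be positive")
    return df


def read_pool_table(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, required=["gene_id", "essential"])
    vals = set(df["essential"].dropna().unique())
    if not vals <= {0, 1, 0.0, 1.0, "0", "1"}:
        raise SchemaError(f"{path}: 'essential' must be 0/1")
    df["essential"] = pd.to_numeric(df["essential"]).astype(int)
    return df


def read_ages_table(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, required=["gene_id", "branch"])
    df["branch"] = pd.to_numeric(df["branch"], errors="raise").astype(int)
    return df


def read_tree(path: str | Path, focal_species: str) -> SpeciesTree:
    return SpeciesTree.from_newick(Path(path), focal_species)
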