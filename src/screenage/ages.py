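"""Origination-branch assignment and lethality tabulation by age/mechanism.

A gene's origination branch is reconstructed under a single-gain model: the
gene arose once, on the branch immediately above the most recent common
ancestor of all species where it is present; absences inside that clade are
explained by losses (counted and reported).  ``unknown`` species states are
ignored when locating the MRCA and never force a loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from screenage.trees import SpeciesTree

__all__ = [
    "GeneAgeRecord",
    "assign_origination_branch",
    "date_genes",
    "tabulate_by_branch",
    "tabulate_by_mechanism",
]

MECHANISMS = ("DNA-duplication", "RNA-duplication", "orphan")

_PRESENT = {"present", "1", 1, True}
_ABSENT = {"absent", "0", 0, False}
_UNKNOWN = {"unknown", "NA", "na", None}


@dataclass(frozen=True)
class GeneAgeRecord:
    gene_id: str
    branch: int
    branch_label: str
    mechanism: str = "unknown"
    n_inferred_losses: int = 0


def _normalize_call(value) -> str:
    if isinstance(value, float):
        if value != value:  # NaN
            return "unknown"
        value = int(value) if value in (0.0, 1.0) else value
    if value in _PRESENT:
        return "present"
    if value in _ABSENT:
        return "absent"
    if value in _UNKNOWN:
        return "unknown"
    raise ValueError(f"invalid presence call {value!r}; expected 1/0/NA")


def assign_origination_branch(
    presence: Mapping[str, object], tree: SpeciesTree
) -> tuple[int, int]:
    """Place a gene's gain branch from its per-species presence calls.

    Parameters
    ----------
    presence:
        Mapping species name -> call in ``{present, absent, unknown}`` (or
        ``{1, 0, NA}``).
    tree:
        The rooted species tree with a focal species.

    Returns
    -------
    (branch_index, n_inferred_losses)
    """
    if not presence:
        raise ValueError("empty presence call set")
    present: set[str] = set()
    absent: set[str] = set()
    for sp, raw in presence.items():
        if sp not in tree.species:
            raise ValueError(f"species {sp!r} not in tree")
        call = _normalize_call(raw)
        if call == "present":
            present.add(sp)
        elif call == "absent":
            absent.add(sp)
    if tree.focal_species not in present:
        raise ValueError(
            f"focal species {tree.focal_species!r} must be present for dating"
        )
    branch = tree.branch_index_of_mrca(present)
    losses = tree.min_losses(branch, present, absent)
    return branch, losses


def date_genes(
    presence_matrix: pd.DataFrame,
    tree: SpeciesTree,
    mechanisms: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Date every row of a gene x species presence matrix.

    ``presence_matrix`` must be indexed by gene id with one column per
    species.  Returns a frame with columns
    ``gene_id, branch, branch_label, mechanism, n_inferred_losses``.
    """
    records = []
    for gene_id, row in presence_matrix.iterrows():
        branch, losses = assign_origination_branch(row.to_dict(), tree)
        mech = (mechanisms or {}).get(gene_id, "unknown")
        records.append(
            {
                "gene_id": gene_id,
                "branch": branch,
                "branch_label": tree.branch_label(branch),
                "mechanism": mech,
                "n_inferred_losses": losses,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["gene_id", "branch", "branch_label", "mechanism", "n_inferred_losses"],
    )


def _check_phenotypes(ages: pd.DataFrame, phenotypes: Mapping[str, str]) -> pd.Series:
    known = set(ages["gene_id"])
    unknown = set(phenotypes) - known
    if unknown:
        raise KeyError(f"phenotype for genes without age records: {sorted(unknown)[:5]}")
    calls = {}
    for gene, call in phenotypes.items():
        if call == "semi-lethal":  # merged downstream into lethal
            call = "lethal"
        if call not in ("lethal", "non-lethal"):
            raise ValueError(f"phenotype for {gene!r} must be lethal/non-lethal, got {call!r}")
        calls[gene] = call
    return pd.Series(calls, name="phenotype")


def _tabulate(ages: pd.DataFrame, phenotypes: Mapping[str, str], key: str) -> pd.DataFrame:
    calls = _check_phenotypes(ages, phenotypes)
    sub = ages.set_index("gene_id").loc[calls.index]
    df = pd.DataFrame({key: sub[key], "lethal": (calls == "lethal").astype(int)})
    out = df.groupby(key, sort=True).agg(n=("lethal", "size"), n_lethal=("lethal", "sum"))
    out["proportion"] = out["n_lethal"] / out["n"]
    return out.reset_index()


def tabulate_by_branch(ages: pd.DataFrame, phenotypes: Mapping[str, str]) -> pd.DataFrame:
    """Per-branch gene counts, lethal counts and lethal proportions."""
    return _tabulate(ages, phenotypes, "branch")


def tabulate_by_mechanism(
    ages: pd.DataFrame,
    phenotypes: Mapping[str, str],
    categories: Iterable[str] = MECHANISMS,
) -> tuple[pd.DataFrame, int]:
    """Per-mechanism tabulation over ``categories``.

    Genes with a mechanism outside ``categories`` (e.g. ``unknown``) are
    excluded from the table; their count is returned separately.
    """
    table = _tabulate(ages, phenotypes, "mechanism")
    keep = table["mechanism"].isin(set(categories))
    n_excluded = int(table.loc[~keep, "n"].sum())
    return table.loc[keep].reset_index(drop=True), n_excluded
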