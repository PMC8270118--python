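"""Phenotype calling, landing-site genotype filtering and screen agreement."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ConcordanceSummary",
    "GenotypeFilterResult",
    "call_phenotype",
    "concordance",
    "gene_level_call",
    "genotype_filter",
]


def call_phenotype(
    gfp_count: int,
    nongfp_count: int,
    lethal_cut: float = 0.1,
    semi_cut: float = 0.5,
) -> str:
    """Call a line's viability from GFP (control) / non-GFP (perturbed) F1 counts.

    The call is based on the survival ratio r = nongfp/gfp: ``lethal`` if
    r < lethal_cut, ``semi-lethal`` if lethal_cut <= r < semi_cut, else
    ``non-lethal``.  A zero GFP count leaves no denominator and the line is
    ``invalid``.  Semi-lethal lines are merged into lethal in downstream
    tabulations.
    """
    if gfp_count < 0 or nongfp_count < 0:
        raise ValueError("progeny counts must be non-negative")
    if not 0 < lethal_cut < semi_cut:
        raise ValueError("need 0 < lethal_cut < semi_cut")
    if gfp_count == 0:
        return "invalid"
    r = nongfp_count / gfp_count
    if r < lethal_cut:
        return "lethal"
    if r < semi_cut:
        return "semi-lethal"
    return "non-lethal"


@dataclass
class GenotypeFilterResult:
    usable: pd.DataFrame
    excluded: pd.DataFrame
    uncalled: pd.DataFrame
    summary: dict = field(default_factory=dict)


def genotype_filter(lines: pd.DataFrame) -> GenotypeFilterResult:
    """Split screen lines into usable / excluded / uncalled by landing site.

    Lines carrying the confounding 40D3 insertion (alone or together with
    30B3) are excluded from lethality inference unless flagged as recombined
    back to a 30B3-only genotype.  Lines with missing insertion flags cannot
    be adjudicated and are routed to ``uncalled``.

    The summary reports, among genotyped lines, the proportion with two
    landing sites and with only the 40D3 site.
    """
    required = {"has_30B3", "has_40D3"}
    missing = required - set(lines.columns)
    if missing:
        raise ValueError(f"missing insertion-flag columns: {sorted(missing)}")
    flags_known = lines["has_30B3"].notna() & lines["has_40D3"].notna()
    uncalled = lines.loc[~flags_known]
    known = lines.loc[flags_known]

    has30 = known["has_30B3"].astype(bool)
    has40 = known["has_40D3"].astype(bool)
    if "recombined" in known.columns:
        recombined = known["recombined"].fillna(False).astype(bool)
    else:
        recombined = pd.Series(False, index=known.index)

    excluded_mask = has40 & ~recombined
    usable = known.loc[~excluded_mask]
    excluded = known.loc[excluded_mask]

    n = len(known)
    n_dual = int((has30 & has40).sum())
    n_40d3_only = int((has40 & ~has30).sum())
    summary = {
        "n_input": len(lines),
        "n_genotyped": n,
        "n_dual_site": n_dual,
        "n_40d3_only": n_40d3_only,
        "pct_dual_site": 100.0 * n_dual / n if n else float("nan"),
        "pct_40d3_only": 100.0 * n_40d3_only / n if n else float("nan"),
        "n_recombined_restored": int((has40 & recombined).sum()),
        "n_usable": len(usable),
        "n_excluded": len(excluded),
        "n_uncalled": len(uncalled),
    }
    return GenotypeFilterResult(usable=usable, excluded=excluded, uncalled=uncalled, summary=summary)


def gene_level_call(line_calls: Iterable[str]) -> str:
    """Collapse usable line calls for one gene: lethal if any line is lethal.

    Semi-lethal counts as lethal; invalid/uncalled lines are ignored.  If no
    informative line remains the gene is ``uncalled``.
    """
    informative = [c for c in line_calls if c in ("lethal", "semi-lethal", "non-lethal")]
    if not informative:
        return "uncalled"
    if any(c in ("lethal", "semi-lethal") for c in informative):
        return "lethal"
    return "non-lethal"


@dataclass(frozen=True)
class ConcordanceSummary:
    n_pairs: int
    n_both_lethal: int
    n_both_nonlethal: int
    n_discordant: int
    percent_agreement: float
    # direction detail: how discordance splits between the two screens
    n_a_lethal_only: int = 0
    n_b_lethal_only: int = 0


def _binary(call: str) -> str:
    if call == "semi-lethal":
        return "lethal"
    if call not in ("lethal", "non-lethal"):
        raise ValueError(f"concordance needs binary calls, got {call!r}")
    return call


def concordance(
    calls_a: Mapping[str, str], calls_b: Mapping[str, str]
) -> ConcordanceSummary:
    """Agreement between two screens' per-gene lethal/non-lethal calls.

    Operates on the intersection of gene ids; symmetric in argument order
    for all count fields except the direction detail.
    """
    shared = sorted(set(calls_a) & set(calls_b))
    if not shared:
        raise ValueError("no shared gene ids between the two call sets")
    both_lethal = both_non = a_only = b_only = 0
    for g in shared:
        a = _binary(calls_a[g])
        b = _binary(calls_b[g])
        if a == b == "lethal":
            both_lethal += 1
        elif a == b == "non-lethal":
            both_non += 1
        elif a == "lethal":
            a_only += 1
        else:
            b_only += 1
    n = len(shared)
    agree = both_lethal + both_non
    return ConcordanceSummary(
        n_pairs=n,
        n_both_lethal=both_lethal,
        n_both_nonlethal=both_non,
        n_discordant=n - agree,
        percent_agreement=100.0 * agree / n,
        n_a_lethal_only=a_only,
        n_b_lethal_only=b_only,
    )
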