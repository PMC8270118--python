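"""Knockdown-efficiency quantification and QC.

Relative expression follows the ΔΔCt convention: per replicate
ΔCt = Ct(target) − Ct(reference), ΔΔCt = mean ΔCt(knockdown) − mean
ΔCt(control), percent-of-control = 100·2^(−ΔΔCt).  Standard errors are
propagated from replicate standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionResult",
    "DistributionComparison",
    "CompensationResult",
    "relative_expression",
    "efficiency_from_qpcr",
    "efficiency_summary",
    "compare_distributions",
    "off_target_flag",
    "compensation_test",
    "welch_t",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class ExpressionResult:
    percent_of_control: float
    se_percent: float
    delta_delta_ct: float
    se_delta_delta_ct: float
    n_knockdown: int
    n_control: int


def _condition_delta_ct(
    wells: pd.DataFrame, role: str, reference_role: str, condition: str
) -> np.ndarray:
    sub = wells[wells["condition"] == condition]
    target = sub[sub["gene_role"] == role].set_index("replicate")["ct"]
    ref = sub[sub["gene_role"] == reference_role].set_index("replicate")["ct"]
    if ref.empty:
        raise ValueError(f"missing reference wells for condition {condition!r}")
    if target.empty:
        raise ValueError(f"missing {role!r} wells for condition {condition!r}")
    common = target.index.intersection(ref.index)
    if len(common) == 0:
        raise ValueError("no replicate pairing between target and reference wells")
    return (target.loc[common] - ref.loc[common]).to_numpy(dtype=float)


def relative_expression(
    wells: pd.DataFrame,
    target_role: str = "target",
    reference_role: str = "reference",
    knockdown_condition: str = "knockdown",
    control_condition: str = "control",
) -> ExpressionResult:
    """Percent-of-control expression of one gene from a table of qPCR wells.

    ``wells`` needs columns ``gene_role, condition, replicate, ct``.  Raises
    if either condition or its reference wells are absent.
    """
    for col in ("gene_role", "condition", "replicate", "ct"):
        if col not in wells.columns:
            raise ValueError(f"qPCR wells missing column {col!r}")
    conditions = set(wells["condition"])
    for cond in (knockdown_condition, control_condition):
        if cond not in conditions:
            raise ValueError(f"wells contain a single condition; missing {cond!r}")
    d_kd = _condition_delta_ct(wells, target_role, reference_role, knockdown_condition)
    d_ct = _condition_delta_ct(wells, target_role, reference_role, control_condition)
    ddct = float(d_kd.mean() - d_ct.mean())

    def _se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0

    se_ddct = math.hypot(_se(d_kd), _se(d_ct))
    percent = 100.0 * 2.0 ** (-ddct)
    return ExpressionResult(
        percent_of_control=percent,
        se_percent=LN2 * percent * se_ddct,
        delta_delta_ct=ddct,
        se_delta_delta_ct=se_ddct,
        n_knockdown=len(d_kd),
        n_control=len(d_ct),
    )


def efficiency_from_qpcr(
    qpcr: pd.DataFrame, target_role: str = "target"
) -> pd.DataFrame:
    """Per-line percent-of-control table from a stacked qPCR well table.

    Expects one block of wells per ``line_id`` (columns ``line_id, gene_id,
    gene_role, condition, replicate, ct``).
    """
    records = []
    for line_id, block in qpcr.groupby("line_id", sort=True):
        res = relative_expression(block, target_role=target_role)
        gene_ids = block.loc[block["gene_role"] == target_role, "gene_id"].unique()
        records.append(
            {
                "line_id": line_id,
                "gene_id": gene_ids[0] if len(gene_ids) else "",
                "percent_of_control": res.percent_of_control,
                "se": res.se_percent,
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["line_id", "gene_id", "percent_of_control", "se"]
    )


def efficiency_summary(
    records: pd.DataFrame,
    thresholds: Sequence[float] = (20.0, 30.0),
    group_col: str = "library",
    value_col: str = "percent_of_control",
) -> pd.DataFrame:
    """Per-group mean efficiency and proportions at or below each threshold."""
    if records.empty:
        raise ValueError("no efficiency records")
    rows = []
    for group, block in records.groupby(group_col, sort=True):
        vals = block[value_col].to_numpy(dtype=float)
        if len(vals) == 0:
            raise ValueError(f"empty group {group!r}")
        row = {group_col: group, "n": len(vals), "mean_percent": float(vals.mean())}
        for thr in thresholds:
            row[f"p_le_{thr:g}"] = float((vals <= thr).mean())
        rows.append(row)
    return pd.DataFrame.from_records(rows)


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t statistic, Welch–Satterthwaite df and two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    denom = va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
    df = (va + vb) ** 2 / denom if denom > 0 else float("nan")
    return float(res.statistic), float(df), float(res.pvalue)


@dataclass
class DistributionComparison:
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    prop_le_a: dict = field(default_factory=dict)
    prop_le_b: dict = field(default_factory=dict)
    z_a: np.ndarray = field(default_factory=lambda: np.array([]))
    z_b: np.ndarray = field(default_factory=lambda: np.array([]))
    qq_probs: np.ndarray = field(default_factory=lambda: np.array([]))
    qq_a: np.ndarray = field(default_factory=lambda: np.array([]))
    qq_b: np.ndarray = field(default_factory=lambda: np.array([]))
    max_qq_deviation: float = float("nan")
    t_stat: float | None = None
    df: float | None = None
    p_value: float | None = None
    degenerate: bool = False


def compare_distributions(
    group_a: Sequence[float],
    group_b: Sequence[float],
    probs: Sequence[float] | None = None,
    thresholds: Sequence[float] = (20.0, 30.0),
    pooled_z: bool = False,
) -> DistributionComparison:
    """Compare two efficiency distributions: means, z-scores, Q-Q, Welch t.

    Quantiles use linear interpolation between order statistics.  Z-scores
    are standardized within each group (``pooled_z=True`` standardizes with
    the pooled mean/SD instead).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if probs is None:
        probs = np.linspace(0.0, 1.0, 101)
    probs = np.asarray(probs, dtype=float)

    if pooled_z:
        pooled = np.concatenate([a, b])
        mu, sd = pooled.mean(), pooled.std(ddof=1)
        z_a, z_b = (a - mu) / sd, (b - mu) / sd
    else:
        z_a = (a - a.mean()) / a.std(ddof=1) if a.std(ddof=1) > 0 else np.zeros_like(a)
        z_b = (b - b.mean()) / b.std(ddof=1) if b.std(ddof=1) > 0 else np.zeros_like(b)

    qa = np.quantile(a, probs, method="linear")
    qb = np.quantile(b, probs, method="linear")

    degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    if degenerate:
        t = df = p = None
    else:
        t, df, p = welch_t(a, b)

    return DistributionComparison(
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        prop_le_a={float(t_): float((a <= t_).mean()) for t_ in thresholds},
        prop_le_b={float(t_): float((b <= t_).mean()) for t_ in thresholds},
        z_a=z_a,
        z_b=z_b,
        qq_probs=probs,
        qq_a=qa,
        qq_b=qb,
        max_qq_deviation=float(np.max(np.abs(qa - qb))),
        t_stat=t,
        df=df,
        p_value=p,
        degenerate=degenerate,
    )


def off_target_flag(
    target_percent: float, paralog_percent: float, margin: float = 1.25
) -> bool:
    """Flag a likely off-target line: paralog knocked down to (near) the
    target's level, i.e. paralog_percent <= margin * target_percent."""
    if target_percent <= 0 or paralog_percent <= 0:
        raise ValueError("percent-of-control values must be positive")
    return paralog_percent <= margin * target_percent


@dataclass
class CompensationResult:
    fold_change: float
    t_stat: float
    p_value: float
    controls: dict
    verdict: str
    alpha: float


def compensation_test(
    paralog_mutant_reps: Sequence[float],
    paralog_wt_reps: Sequence[float],
    control_genes: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    alpha: float = 0.01,
) -> CompensationResult:
    """Test for transcriptional compensation of a paralog in a knockout.

    Verdict is ``compensation`` iff the paralog is significantly upregulated
    (two-sided Welch t, p < alpha, fold change > 1) while every control gene
    is non-significant at the same alpha; ``ambiguous`` if the paralog is
    significant but some control is too; otherwise ``none``.
    """
    mut = np.asarray(paralog_mutant_reps, dtype=float)
    wt = np.asarray(paralog_wt_reps, dtype=float)
    if len(mut) < 3 or len(wt) < 3:
        raise ValueError("insufficient replicates: need >= 3 per condition")
    fold = float(mut.mean() / wt.mean())
    t, _, p = welch_t(mut, wt)

    controls: dict = {}
    any_control_sig = False
    for name, (c_mut, c_wt) in control_genes.items():
        c_mut = np.asarray(c_mut, dtype=float)
        c_wt = np.asarray(c_wt, dtype=float)
        if len(c_mut) < 3 or len(c_wt) < 3:
            raise ValueError(f"insufficient replicates for control {name!r}")
        ct, _, cp = welch_t(c_mut, c_wt)
        controls[name] = {
            "fold_change": float(c_mut.mean() / c_wt.mean()),
            "t_stat": ct,
            "p_value": cp,
        }
        if cp < alpha:
            any_control_sig = True

    paralog_sig = p < alpha and fold > 1.0
    if paralog_sig and not any_control_sig:
        verdict = "compensation"
    elif paralog_sig:
        verdict = "ambiguous"
    else:
        verdict = "none"
    return CompensationResult(
        fold_change=fold, t_stat=t, p_value=p, controls=controls, verdict=verdict, alpha=alpha
    )
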