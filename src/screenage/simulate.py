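"""Seeded forward simulator for a complete screen dataset with ground truth.

Generates, from one :class:`SimulationConfig`: a species tree, a gene x
species presence/absence matrix consistent with per-gene origination
branches (single gain, optional stochastic losses), per-gene essentiality
and origination mechanism, per-line knockdown efficiencies drawn from
library-specific Beta distributions, lethal/non-lethal screen calls with
efficiency-dependent false negatives, off-target-style false positives and
40D3 landing-site artifacts, qPCR Ct wells for a subset of lines, and
knockout expression tables with paralog compensation above a similarity
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special, stats

from screenage.trees import SpeciesTree

__all__ = [
    "SimulationConfig",
    "SimulatedBundle",
    "simulate_dataset",
    "simulate_qpcr",
    "beta_params_for_mean",
    "beta_params_for_detection",
    "DEFAULT_NEWICK",
]

# 12-species tree with a 6-stage root-to-focal path (branch 0 = above root).
DEFAULT_NEWICK = (
    "((((((D_melanogaster,(D_simulans,D_sechellia)),(D_yakuba,D_erecta)),"
    "D_ananassae),(D_pseudoobscura,D_persimilis)),D_willistoni),"
    "(D_virilis,(D_mojavensis,D_grimshawi)));"
)
DEFAULT_FOCAL = "D_melanogaster"

MECHANISMS = ("DNA-duplication", "RNA-duplication", "orphan")

BASE_CT_REFERENCE = 16.0
BASE_CT_TARGET = 24.0


def beta_params_for_mean(mean: float, concentration: float = 3.0) -> tuple[float, float]:
    """Beta shape parameters with the given mean (on (0,1)) and a+b=concentration."""
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must be in (0, 1)")
    return mean * concentration, (1.0 - mean) * concentration


def beta_params_for_detection(
    tau: float, detect_prob: float, concentration: float = 3.0
) -> tuple[float, float]:
    """Beta shape parameters such that P(100*X <= tau) equals ``detect_prob``.

    Solves for the Beta mean at fixed concentration by bisection; used to
    plant a known false-negative rate (1 - detect_prob) in simulations.
    """
    x = tau / 100.0
    if not 0.0 < x < 1.0:
        raise ValueError("tau must be in (0, 100)")
    if not 0.0 < detect_prob < 1.0:
        raise ValueError("detect_prob must be in (0, 1)")

    def f(mu: float) -> float:
        a, b = mu * concentration, (1.0 - mu) * concentration
        return stats.beta.cdf(x, a, b) - detect_prob

    mu = optimize.brentq(f, 1e-6, 1.0 - 1e-6)
    return mu * concentration, (1.0 - mu) * concentration


def _check_probs(name: str, probs, length: int | None = None) -> np.ndarray:
    arr = np.asarray(probs, dtype=float)
    if length is not None and len(arr) != length:
        raise ValueError(f"{name} must have length {length}, got {len(arr)}")
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError(f"{name} entries must be in [0, 1]")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {arr.sum()})")
    return arr


@dataclass
class SimulationConfig:
    """Parameters of one synthetic screen dataset (all randomness is seeded)."""

    n_genes: int = 1000
    newick: str = DEFAULT_NEWICK
    focal_species: str = DEFAULT_FOCAL
    # per-branch gene origination probabilities, length K+1 (0 = pre-root)
    branch_probs: tuple = (0.0, 0.25, 0.15, 0.15, 0.15, 0.15, 0.15)
    p_essential_per_branch: tuple = (0.2, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2)
    mechanism_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "DNA-duplication": 0.55,
            "RNA-duplication": 0.25,
            "orphan": 0.20,
        }
    )
    # per-library Beta shape parameters of percent-of-control/100
    efficiency_params: Mapping[str, tuple] = field(
        default_factory=lambda: {
            "GD": beta_params_for_mean(0.381),
            "KK": beta_params_for_mean(0.486),
        }
    )
    library_probs: Mapping[str, float] = field(
        default_factory=lambda: {"GD": 0.5, "KK": 0.5}
    )
    detection_threshold: float = 30.0  # tau: percent-of-control cutoff
    detection_mode: str = "hard"  # "hard" | "sigmoid"
    sigmoid_width: float = 5.0
    fp_rate: float = 0.016
    p_40d3: float = 0.24
    p_recombined: float = 0.0
    loss_rate: float = 0.0
    ct_noise_sd: float = 0.15
    compensation_factor: float = 2.0
    paralog_fraction: float = 0.0
    similarity_threshold: float = 0.9
    n_qpcr_lines: int = 0
    qpcr_reps: int = 3
    knockout_reps: int = 3
    expression_cv: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        tree = self.tree()
        k = tree.n_branches
        _check_probs("branch_probs", self.branch_probs, k + 1)
        pe = np.asarray(self.p_essential_per_branch, dtype=float)
        if len(pe) != k + 1 or (pe < 0).any() or (pe > 1).any():
            raise ValueError("p_essential_per_branch must be K+1 probabilities in [0,1]")
        mp = _check_probs("mechanism_probs", list(self.mechanism_probs.values()))
        del mp
        _check_probs("library_probs", list(self.library_probs.values()))
        if not 0.0 < self.detection_threshold < 100.0:
            raise ValueError("detection_threshold must be in (0, 100)")
        if self.detection_mode not in ("hard", "sigmoid"):
            raise ValueError("detection_mode must be 'hard' or 'sigmoid'")
        for name in ("fp_rate", "p_40d3", "p_recombined", "loss_rate", "paralog_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.compensation_factor < 1.0:
            raise ValueError("compensation_factor must be >= 1")
        for lib, ab in self.efficiency_params.items():
            a, b = ab
            if a <= 0 or b <= 0:
                raise ValueError(f"efficiency_params[{lib}] must be positive shapes")

    def tree(self) -> SpeciesTree:
        return SpeciesTree.from_newick(self.newick, self.focal_species)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["mechanism_probs"] = dict(self.mechanism_probs)
        d["efficiency_params"] = {k: list(v) for k, v in self.efficiency_params.items()}
        d["library_probs"] = dict(self.library_probs)
        d["branch_probs"] = list(self.branch_probs)
        d["p_essential_per_branch"] = list(self.p_essential_per_branch)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        d = yaml.safe_load(text)
        if "efficiency_params" in d:
            d["efficiency_params"] = {
                k: tuple(v) for k, v in d["efficiency_params"].items()
            }
        for key in ("branch_probs", "p_essential_per_branch"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def simulate_qpcr(
    efficiency: float,
    n_reps: int = 3,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    line_id: str = "line",
    gene_id: str = "gene",
) -> pd.DataFrame:
    """Ct wells for target/reference x knockdown/control at a planted efficiency.

    The knockdown target Ct is shifted by -log2(efficiency/100) cycles above
    the control baseline, so running the ΔΔCt computation on noise-free
    output recovers the input efficiency exactly.
    """
    if efficiency <= 0 or efficiency > 200:
        raise ValueError("efficiency must be in (0, 200] percent of control")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    shift = -math.log2(efficiency / 100.0)
    rows = []
    for condition in ("control", "knockdown"):
        for role, base in (("target", BASE_CT_TARGET), ("reference", BASE_CT_REFERENCE)):
            ct = base + (shift if (condition == "knockdown" and role == "target") else 0.0)
            for rep in range(1, n_reps + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append(
                    {
                        "sample_id": f"{line_id}_{condition}",
                        "line_id": line_id,
                        "gene_id": gene_id if role == "target" else "RpL32",
                        "gene_role": role,
                        "condition": condition,
                        "replicate": rep,
                        "ct": ct + noise,
                    }
                )
    return pd.DataFrame.from_records(
        rows,
        columns=["sample_id", "line_id", "gene_id", "gene_role", "condition", "replicate", "ct"],
    )


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    newick: str
    presence: pd.DataFrame  # index gene_id, columns species, values 1/0
    annotations: pd.DataFrame  # gene_id, mechanism
    screens: pd.DataFrame
    qpcr: pd.DataFrame
    knockout: pd.DataFrame
    truth_genes: pd.DataFrame
    truth_lines: pd.DataFrame

    def write(self, outdir: str | Path) -> Path:
        """Write every table as TSV (plus newick tree and YAML config echo)."""
        from screenage import io as sio

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(self.newick + "\n")
        sio.write_tsv(self.presence.reset_index(), out / "presence.tsv")
        sio.write_tsv(self.annotations, out / "annotations.tsv")
        sio.write_tsv(self.screens, out / "screens.tsv")
        sio.write_tsv(self.qpcr, out / "qpcr.tsv")
        sio.write_tsv(self.knockout, out / "knockout.tsv")
        sio.write_tsv(self.truth_genes, out / "truth_genes.tsv")
        sio.write_tsv(self.truth_lines, out / "truth_lines.tsv")
        (out / "config.yaml").write_text(self.config.to_yaml())
        return out


def simulate_dataset(config: SimulationConfig) -> SimulatedBundle:
    """Generate a full synthetic dataset; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    tree = config.tree()
    k = tree.n_branches
    n = config.n_genes
    species = sorted(tree.species)
    focal = tree.focal_species

    gene_ids = np.array([f"g{i:05d}" for i in range(1, n + 1)])
    branch_probs = np.asarray(config.branch_probs, dtype=float)
    p_ess = np.asarray(config.p_essential_per_branch, dtype=float)
    branches = rng.choice(k + 1, size=n, p=branch_probs)
    essential = rng.random(n) < p_ess[branches]
    mech_names = list(config.mechanism_probs)
    mechanisms = rng.choice(
        mech_names, size=n, p=list(config.mechanism_probs.values())
    )

    # presence matrix: species under the gain branch's clade, focal always kept
    clade = np.zeros((k + 1, len(species)), dtype=bool)
    for b in range(k + 1):
        members = tree.clade_species(b)
        clade[b] = [sp in members for sp in species]
    presence = clade[branches].copy()
    if config.loss_rate > 0:
        flip = rng.random(presence.shape) < config.loss_rate
        not_focal = np.array([sp != focal for sp in species])
        presence &= ~(flip & not_focal)
    presence_df = pd.DataFrame(
        presence.astype(int), index=pd.Index(gene_ids, name="gene_id"), columns=species
    )

    # one screen line per gene
    line_ids = np.array([f"L{i:05d}" for i in range(1, n + 1)])
    libs = np.array(list(config.library_probs))
    library = rng.choice(libs, size=n, p=list(config.library_probs.values()))
    efficiency = np.empty(n, dtype=float)
    for lib in libs:
        mask = library == lib
        a, b = config.efficiency_params[lib]
        efficiency[mask] = 100.0 * rng.beta(a, b, size=int(mask.sum()))

    is_kk = library == "KK"
    has_30b3 = is_kk.copy()
    has_40d3 = is_kk & (rng.random(n) < config.p_40d3)
    recombined = has_40d3 & (rng.random(n) < config.p_recombined)
    confounded = has_40d3 & ~recombined

    if config.detection_mode == "hard":
        detected = efficiency <= config.detection_threshold
    else:
        p_det = special.expit(
            (config.detection_threshold - efficiency) / config.sigmoid_width
        )
        detected = rng.random(n) < p_det
    false_positive = ~essential & (rng.random(n) < config.fp_rate)
    lethal = (essential & detected) | false_positive
    lethal = lethal | confounded  # un-recombined 40D3 insertion is itself lethal

    gfp = rng.poisson(100, size=n) + 20
    nongfp = np.where(
        lethal, rng.binomial(gfp, 0.01), rng.binomial(gfp, 0.95)
    )
    screens = pd.DataFrame(
        {
            "line_id": line_ids,
            "gene_id": gene_ids,
            "library": library,
            "has_30B3": has_30b3.astype(int),
            "has_40D3": has_40d3.astype(int),
            "recombined": recombined.astype(int),
            "driver": "Act5C-GAL4",
            "gfp_count": gfp,
            "nongfp_count": nongfp,
            "phenotype": np.where(lethal, "lethal", "non-lethal"),
        }
    )

    # qPCR wells for a subset of non-confounded KK lines (efficiency assay)
    qpcr_frames = []
    candidates = np.flatnonzero(is_kk & ~confounded)
    n_qpcr = min(config.n_qpcr_lines, len(candidates))
    if n_qpcr > 0:
        chosen = rng.choice(candidates, size=n_qpcr, replace=False)
        for idx in sorted(chosen):
            qpcr_frames.append(
                simulate_qpcr(
                    efficiency[idx],
                    n_reps=config.qpcr_reps,
                    noise_sd=config.ct_noise_sd,
                    rng=rng,
                    line_id=str(line_ids[idx]),
                    gene_id=str(gene_ids[idx]),
                )
            )
    qpcr = (
        pd.concat(qpcr_frames, ignore_index=True)
        if qpcr_frames
        else pd.DataFrame(
            columns=["sample_id", "line_id", "gene_id", "gene_role", "condition", "replicate", "ct"]
        )
    )

    # knockout expression for paralog pairs among young genes
    young = np.flatnonzero(branches >= 1)
    n_pairs = int(round(config.paralog_fraction * len(young)))
    ko_rows = []
    similarity = np.full(n, np.nan)
    compensated = np.zeros(n, dtype=bool)
    if n_pairs > 0:
        pair_idx = rng.choice(young, size=n_pairs, replace=False)
        similarity[pair_idx] = rng.uniform(0.5, 1.0, size=n_pairs)
        compensated[pair_idx] = similarity[pair_idx] >= config.similarity_threshold
        for idx in sorted(pair_idx):
            gid = gene_ids[idx]
            assays = [
                ("paralog", config.compensation_factor if compensated[idx] else 1.0),
                ("unrelated", 1.0),
                ("remote", 1.0),
            ]
            for role, mut_mean in assays:
                for condition, mean in (("wildtype", 1.0), ("mutant", mut_mean)):
                    reps = rng.normal(
                        mean, config.expression_cv * mean, size=config.knockout_reps
                    )
                    for r, val in enumerate(reps, start=1):
                        ko_rows.append(
                            {
                                "mutant_gene": gid,
                                "assayed_role": role,
                                "similarity": round(float(similarity[idx]), 4),
                                "condition": condition,
                                "replicate": r,
                                "expression": float(val),
                            }
                        )
    knockout = pd.DataFrame.from_records(
        ko_rows,
        columns=["mutant_gene", "assayed_role", "similarity", "condition", "replicate", "expression"],
    )

    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "branch": branches,
            "essential": essential.astype(int),
            "mechanism": mechanisms,
            "paralog_similarity": similarity,
            "compensated": compensated.astype(int),
        }
    )
    truth_lines = pd.DataFrame(
        {
            "line_id": line_ids,
            "gene_id": gene_ids,
            "library": library,
            "true_efficiency": efficiency,
            "detected": detected.astype(int),
            "false_positive": false_positive.astype(int),
            "has_40D3": has_40d3.astype(int),
            "confounded": confounded.astype(int),
        }
    )

    return SimulatedBundle(
        config=config,
        newick=config.newick,
        presence=presence_df,
        annotations=pd.DataFrame({"gene_id": gene_ids, "mechanism": mechanisms}),
        screens=screens,
        qpcr=qpcr,
        knockout=knockout,
        truth_genes=truth_genes,
        truth_lines=truth_lines,
    )
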