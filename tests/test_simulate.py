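import filecmp
import math
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from oracles import qpcr_roundtrip_se

from screenage import (
    SimulationConfig,
    beta_params_for_detection,
    beta_params_for_mean,
    relative_expression,
    simulate_dataset,
    simulate_qpcr,
)


class TestConfigValidation:
    def test_defaults_are_valid(self):
        cfg = SimulationConfig()
        assert cfg.tree().n_branches == 6

    def test_nonpositive_n_genes(self):
        with pytest.raises(ValueError, match="n_genes"):
            SimulationConfig(n_genes=0)

    def test_branch_probs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="branch_probs"):
            SimulationConfig(branch_probs=(0.5, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1))

    def test_branch_probs_length_checked(self):
        with pytest.raises(ValueError, match="length"):
            SimulationConfig(branch_probs=(0.5, 0.5))

    def test_mechanism_probs_checked(self):
        with pytest.raises(ValueError, match="mechanism_probs"):
            SimulationConfig(mechanism_probs={"DNA-duplication": 0.9, "orphan": 0.2})

    def test_threshold_range(self):
        with pytest.raises(ValueError):
            SimulationConfig(detection_threshold=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(detection_threshold=150.0)

    def test_compensation_factor_floor(self):
        with pytest.raises(ValueError):
            SimulationConfig(compensation_factor=0.5)

    def test_yaml_roundtrip(self):
        cfg = SimulationConfig(n_genes=123, seed=42, loss_rate=0.05)
        again = SimulationConfig.from_yaml(cfg.to_yaml())
        assert again == cfg


def beta_mean_params(mean):
    return beta_params_for_mean(mean)


class TestBetaCalibration:
    def test_mean_parameterization(self):
        a, b = beta_params_for_mean(0.381)
        assert a / (a + b) == pytest.approx(0.381)

    def test_detection_parameterization(self):
        a, b = beta_params_for_detection(30.0, 0.53)
        assert stats.beta.cdf(0.30, a, b) == pytest.approx(0.53, abs=1e-9)


class TestSimulateDataset:
    def test_perfect_detection_no_fp_observed_equals_truth(self):
        cfg = SimulationConfig(
            n_genes=800,
            seed=3,
            fp_rate=0.0,
            p_40d3=0.0,
            detection_threshold=99.999,
        )
        bundle = simulate_dataset(cfg)
        lethal = (bundle.screens["phenotype"] == "lethal").sum()
        assert lethal == bundle.truth_genes["essential"].sum()

    def test_no_essential_no_fp_zero_lethal(self):
        cfg = SimulationConfig(
            n_genes=500,
            seed=4,
            fp_rate=0.0,
            p_40d3=0.0,
            p_essential_per_branch=(0.0,) * 7,
        )
        bundle = simulate_dataset(cfg)
        assert (bundle.screens["phenotype"] == "lethal").sum() == 0

    def test_observed_lethal_rate_matches_closed_form(self):
        """n=5000, p_ess=0.35, P(eff<=tau)=0.53, fp=0.016 -> observed rate
        within 3 binomial SDs of 0.35*0.53 + 0.65*0.016."""
        eff = beta_params_for_detection(30.0, 0.53)
        cfg = SimulationConfig(
            n_genes=5000,
            seed=1,
            p_essential_per_branch=(0.35,) * 7,
            efficiency_params={"GD": eff, "KK": eff},
            fp_rate=0.016,
            p_40d3=0.0,
        )
        bundle = simulate_dataset(cfg)
        expected = 0.35 * 0.53 + 0.65 * 0.016
        observed = (bundle.screens["phenotype"] == "lethal").mean()
        sd = math.sqrt(expected * (1 - expected) / 5000)
        assert abs(observed - expected) <= 3 * sd

    def test_40d3_lines_always_lethal_unless_recombined(self):
        cfg = SimulationConfig(n_genes=1000, seed=5, p_40d3=0.5, p_recombined=0.4)
        bundle = simulate_dataset(cfg)
        merged = bundle.screens.merge(bundle.truth_lines[["line_id", "confounded"]])
        confounded = merged[merged["confounded"] == 1]
        assert len(confounded) > 0
        assert (confounded["phenotype"] == "lethal").all()
        recombined = merged[(merged["has_40D3"] == 1) & (merged["recombined"] == 1)]
        assert len(recombined) > 0
        assert (recombined["phenotype"] == "non-lethal").any()

    def test_presence_consistent_with_branches(self):
        cfg = SimulationConfig(n_genes=200, seed=6)
        bundle = simulate_dataset(cfg)
        tree = cfg.tree()
        for _, row in bundle.truth_genes.iterrows():
            clade = tree.clade_species(int(row["branch"]))
            present = {
                sp
                for sp in bundle.presence.columns
                if bundle.presence.loc[row["gene_id"], sp] == 1
            }
            assert present == set(clade)

    def test_every_line_references_a_simulated_gene(self):
        bundle = simulate_dataset(SimulationConfig(n_genes=100, seed=7))
        assert set(bundle.screens["gene_id"]) <= set(bundle.truth_genes["gene_id"])
        assert len(bundle.truth_genes) == 100

    def test_line_count_conservation(self):
        from screenage import call_phenotype, genotype_filter

        bundle = simulate_dataset(SimulationConfig(n_genes=400, seed=8, p_40d3=0.3))
        res = genotype_filter(bundle.screens)
        s = res.summary
        assert s["n_usable"] + s["n_excluded"] + s["n_uncalled"] == 400
        calls = [
            call_phenotype(int(g), int(n))
            for g, n in zip(res.usable["gfp_count"], res.usable["nongfp_count"])
        ]
        counted = sum(c in ("lethal", "semi-lethal", "non-lethal", "invalid") for c in calls)
        assert counted == len(res.usable)

    def test_seed_determinism_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(
            n_genes=150, seed=9, n_qpcr_lines=10, paralog_fraction=0.1
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_dataset(cfg).write(d1)
        simulate_dataset(cfg).write(d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files
        for name in files:
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_compensation_only_above_similarity_threshold(self):
        cfg = SimulationConfig(
            n_genes=400, seed=10, paralog_fraction=0.3, compensation_factor=2.5
        )
        bundle = simulate_dataset(cfg)
        truth = bundle.truth_genes.dropna(subset=["paralog_similarity"])
        assert (
            (truth["paralog_similarity"] >= cfg.similarity_threshold)
            == (truth["compensated"] == 1)
        ).all()
        ko = bundle.knockout
        comp_genes = set(truth.loc[truth["compensated"] == 1, "gene_id"])
        for gid, block in ko.groupby("mutant_gene"):
            para = block[block["assayed_role"] == "paralog"]
            mut = para.loc[para["condition"] == "mutant", "expression"].mean()
            wt = para.loc[para["condition"] == "wildtype", "expression"].mean()
            if gid in comp_genes:
                assert mut / wt > 1.5
            else:
                assert 0.7 < mut / wt < 1.3


class TestSimulateQpcr:
    def test_efficiency_50_shifts_target_by_one_cycle(self):
        wells = simulate_qpcr(50.0, n_reps=3, noise_sd=0.0, seed=0)
        kd = wells[(wells.condition == "knockdown") & (wells.gene_role == "target")]
        ctrl = wells[(wells.condition == "control") & (wells.gene_role == "target")]
        assert (kd["ct"].to_numpy() - ctrl["ct"].to_numpy() == 1.0).all()

    def test_efficiency_100_gives_zero_ddct(self):
        wells = simulate_qpcr(100.0, n_reps=3, noise_sd=0.0, seed=0)
        assert relative_expression(wells).delta_delta_ct == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("eff", [5.0, 25.0, 50.0, 99.0, 150.0])
    def test_noise_free_roundtrip_exact(self, eff):
        wells = simulate_qpcr(eff, n_reps=4, noise_sd=0.0, seed=0)
        rec = relative_expression(wells)
        assert rec.percent_of_control == pytest.approx(eff, rel=1e-9)

    def test_noisy_roundtrip_within_propagated_error(self):
        eff, sd, reps = 25.0, 0.2, 3
        wells = simulate_qpcr(eff, n_reps=reps, noise_sd=sd, seed=7)
        rec = relative_expression(wells)
        assert abs(rec.percent_of_control - eff) <= 3 * qpcr_roundtrip_se(eff, sd, reps)

    def test_invalid_efficiency_raises(self):
        with pytest.raises(ValueError):
            simulate_qpcr(0.0)
        with pytest.raises(ValueError):
            simulate_qpcr(-5.0)
        with pytest.raises(ValueError):
            simulate_qpcr(250.0)


def test_roundtrip_corrected_estimate_recovers_truth_small():
    """Single-seed version of the full parameter-recovery loop (the 200-seed
    average is exercised in the acceptance suite)."""
    from screenage import CorrectionParams, call_phenotype, corrected_proportion, genotype_filter

    eff = beta_params_for_detection(30.0, 0.53)
    cfg = SimulationConfig(
        n_genes=5000,
        seed=77,
        p_essential_per_branch=(0.35,) * 7,
        efficiency_params={"GD": eff, "KK": eff},
        fp_rate=0.016,
    )
    bundle = simulate_dataset(cfg)
    usable = genotype_filter(bundle.screens).usable
    calls = [
        call_phenotype(int(g), int(n))
        for g, n in zip(usable["gfp_count"], usable["nongfp_count"])
    ]
    e = sum(c in ("lethal", "semi-lethal") for c in calls)
    t = sum(c != "invalid" for c in calls)
    est = corrected_proportion(e, t, CorrectionParams(0.016, 0.47))
    assert abs(est - 0.35) < 0.05
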