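import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from m6adecay.core_io import AnalysisConfig, ValidationError
from m6adecay.merip import (
    classify_genes,
    compute_enrichment,
    differential_methylation,
    merip_qpcr_fold_enrichment,
    replicate_enrichment_qvalues,
    significant_features,
)
from m6adecay.simulate import SimulationParams, simulate_merip_counts, simulate_transcriptome
from conftest import make_matrix


class TestComputeEnrichment:
    def test_hand_worked_equal_depth(self, tiny_merip):
        # depth-equal libraries: enrichment is just log2 of the count ratio
        enr = compute_enrichment(tiny_merip, "control", pseudocount=0.0)
        assert enr.loc["g0", "log2_enrichment"] == pytest.approx(np.log2(800 / 200))
        assert enr.loc["g1", "log2_enrichment"] == pytest.approx(np.log2(200 / 800))

    def test_depth_invariance(self, tiny_merip):
        doubled = make_matrix(
            {
                "c_in": [400, 1600],
                "c_ip": [800, 200],
                "p_in": [800, 200],
                "p_ip": [200, 800],
            },
            [
                ("c_in", "control", "input"),
                ("c_ip", "control", "IP"),
                ("p_in", "patient", "input"),
                ("p_ip", "patient", "IP"),
            ],
        )
        a = compute_enrichment(tiny_merip, "control", pseudocount=0.0)
        b = compute_enrichment(doubled, "control", pseudocount=0.0)
        assert np.allclose(a.log2_enrichment, b.log2_enrichment)

    def test_missing_assay_errors(self, tiny_merip):
        no_ip = tiny_merip.select_samples(assay="input")
        with pytest.raises(ValidationError, match="IP"):
            compute_enrichment(no_ip, "control")


class TestDetection:
    def test_significant_features_strictness_and_support(self):
        q = pd.DataFrame(
            {
                "control/rep1": [0.001, 0.05, 0.001],
                "control/rep2": [0.005, 0.001, 0.02],
                "control/rep3": [0.009, 0.001, 0.001],
            },
            index=["hit", "two_reps", "two_reps_b"],
        )
        assert significant_features(q, 0.01, 3) == {"hit"}
        assert significant_features(q, 0.01, 2) == {"hit", "two_reps", "two_reps_b"}
        with pytest.raises(ValidationError):
            significant_features(q, 0.01, 4)

    def test_boundary_q_equal_threshold_not_significant(self):
        q = pd.DataFrame({"c/rep1": [0.01]}, index=["edge"])
        assert significant_features(q, 0.01, 1) == set()

    def test_recovers_methylated_features(self, default_study, default_truth):
        q = replicate_enrichment_qvalues(default_study.merip)
        called = significant_features(q, 0.01, 3)
        methylated = set(default_truth.index[default_truth.m_control > 0])
        unmethylated = set(default_truth.index) - methylated
        # methylated features enrich strongly (alpha=8): near-complete recall,
        # and no unmethylated feature should survive q<0.01 in 3 replicates
        assert len(called & methylated) / len(methylated) > 0.95
        assert len(called & unmethylated) == 0

    def test_unmatched_ip_replicate_errors(self):
        broken = make_matrix(
            {"c_ip": [800, 200], "p_in": [800, 200], "p_ip": [200, 800]},
            [
                ("c_ip", "control", "IP"),
                ("p_in", "patient", "input"),
                ("p_ip", "patient", "IP"),
            ],
        )
        with pytest.raises(ValidationError, match="matched input"):
            replicate_enrichment_qvalues(broken)


class TestDifferentialMethylation:
    def test_hand_worked_crossover_table(self, tiny_merip):
        dm = differential_methylation(
            tiny_merip, "control", "patient", method="pooled", center=False
        )
        assert dm.loc["g0", "delta_log2"] == pytest.approx(-4.0, abs=0.01)
        assert dm.loc["g1", "delta_log2"] == pytest.approx(4.0, abs=0.01)
        assert dm.loc["g0", "class"] == "hypo"
        assert dm.loc["g1", "class"] == "hyper"
        assert (dm.p < 1e-50).all()

    def test_pooled_z_agrees_with_fisher_on_moderate_table(self):
        # one informative feature among stable ones; compare the pooled
        # two-proportion z p-value with Fisher's exact on the same 2x2 table
        m = make_matrix(
            {"c_in": [70, 500], "c_ip": [30, 500], "p_in": [50, 500], "p_ip": [50, 500]},
            [
                ("c_in", "control", "input"),
                ("c_ip", "control", "IP"),
                ("p_in", "patient", "input"),
                ("p_ip", "patient", "IP"),
            ],
        )
        dm = differential_methylation(m, "control", "patient", method="pooled", center=False)
        _, p_fisher = sps.fisher_exact([[30, 70], [50, 50]])
        # the z statistic uses whole-library totals (not just the 2x2 margins),
        # so require agreement in scale rather than value
        assert 1 / 3 < dm.loc["g0", "p"] / p_fisher < 3
        assert dm.loc["g1", "p"] > 0.05  # the stable feature stays null

    def test_null_no_calls_and_uniformish_p(self):
        p = SimulationParams(seed=11, hypo_fraction=0.0)
        gt = simulate_transcriptome(p)
        m = simulate_merip_counts(gt, p)
        dm = differential_methylation(m, "control", "patient")
        assert (dm["class"] == "unchanged").all()
        frac = float((dm.p < 0.05).mean())
        # calibrated test: fraction below 0.05 within binomial 99.9% band
        assert abs(frac - 0.05) < 3.3 * np.sqrt(0.05 * 0.95 / len(dm))

    def test_empirical_fdr_controlled(self, default_study, default_truth):
        dm = differential_methylation(default_study.merip, "control", "patient")
        called = dm.index[dm["class"] == "hypo"]
        if len(called):
            fd = (~default_truth.loc[called, "is_hypo"]).mean()
            assert fd <= 0.34  # FDR 0.01 target; small-call-count slack
        hyper = dm.index[dm["class"] == "hyper"]
        assert default_truth.loc[hyper, "is_hypo"].sum() == 0

    def test_zero_input_features_dropped(self, tiny_merip):
        counts = tiny_merip.counts.copy()
        counts.loc["g2"] = 0
        counts.loc["g2", ["c_ip", "p_ip"]] = [5, 5]
        m = make_matrix(
            {c: counts[c].tolist() for c in counts.columns},
            [(s.sample_id, s.condition, s.assay) for s in tiny_merip.samples],
        )
        dm = differential_methylation(m, "control", "patient")
        assert "g2" not in dm.index
        assert set(dm.index) == {"g0", "g1"}

    def test_bad_method_rejected(self, tiny_merip):
        with pytest.raises(ValidationError):
            differential_methylation(tiny_merip, "control", "patient", method="exact")


class TestClassifyGenes:
    def test_peak_to_gene_any_hypo_rule(self):
        calls = pd.DataFrame(
            {"class": ["hypo", "unchanged", "hyper", "unchanged"]},
            index=["pk1", "pk2", "pk3", "pk4"],
        )
        mapping = {"pk1": "gA", "pk2": "gA", "pk3": "gB", "pk4": "gC"}
        lab = classify_genes(calls, mapping)
        assert lab["gA"] == "hypo"
        assert lab["gB"] == "non_hypo"
        assert lab["gC"] == "non_hypo"

    def test_exclude_hyper_drops_pure_hyper_gene(self):
        calls = pd.DataFrame({"class": ["hyper", "hypo"]}, index=["pk1", "pk2"])
        mapping = {"pk1": "gB", "pk2": "gA"}
        lab = classify_genes(calls, mapping, exclude_hyper=True)
        assert "gB" not in lab.index
        assert lab["gA"] == "hypo"

    def test_unmapped_peak_errors(self):
        calls = pd.DataFrame({"class": ["hypo"]}, index=["pk1"])
        with pytest.raises(ValidationError, match="pk1"):
            classify_genes(calls, {"other": "g"})


class TestQpcr:
    def test_hand_worked_double_delta_ct(self):
        # (20-18) - (24-18) = -4 cycles => 2^4 = 16-fold enrichment
        assert merip_qpcr_fold_enrichment(20, 18, 24, 18) == pytest.approx(16.0)

    def test_no_enrichment_is_fold_one(self):
        assert merip_qpcr_fold_enrichment(20, 18, 22, 20) == pytest.approx(1.0)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValidationError):
            merip_qpcr_fold_enrichment(np.nan, 18, 24, 18)
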