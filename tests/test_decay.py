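import numpy as np
import pandas as pd
import pytest

from m6adecay.core_io import AnalysisConfig, SpikeInReference, ValidationError
from m6adecay.decay import (
    CalibrationFit,
    compare_half_life_groups,
    cpm_to_attomole,
    estimate_half_lives,
    estimate_kdecay,
    fit_spikein_calibration,
    half_life,
)
from m6adecay.simulate import (
    SimulationParams,
    simulate_decay_timecourse,
    simulate_transcriptome,
    spikein_reference,
)
from conftest import make_matrix

LN2 = np.log(2.0)


class TestKdecay:
    def test_exact_exponential_recovered(self):
        k_true = 0.23
        t = [0.0, 3.0, 6.0]
        c = 5.0 * np.exp(-k_true * np.asarray(t))
        k, n = estimate_kdecay(c, t)
        assert k == pytest.approx(k_true, rel=1e-12)
        assert n == 2

    def test_rate_averaging_is_mean_of_per_timepoint_rates(self):
        # non-exponential trajectory: definition check, K = mean(K_3, K_6)
        c = [8.0, 4.0, 3.0]
        t = [0.0, 3.0, 6.0]
        k3 = -np.log(4 / 8) / 3
        k6 = -np.log(3 / 8) / 6
        k, _ = estimate_kdecay(c, t, averaging="rate")
        assert k == pytest.approx((k3 + k6) / 2)

    def test_halflife_averaging_is_ln2_over_mean_halflife(self):
        c = [8.0, 4.0, 3.0]
        t = [0.0, 3.0, 6.0]
        k3 = -np.log(4 / 8) / 3
        k6 = -np.log(3 / 8) / 6
        k, _ = estimate_kdecay(c, t, averaging="halflife")
        assert k == pytest.approx(LN2 / np.mean([LN2 / k3, LN2 / k6]))

    def test_both_averagings_agree_on_true_exponential(self):
        c = 2.0 * np.exp(-0.4 * np.array([0.0, 3.0, 6.0]))
        kr, _ = estimate_kdecay(c, [0, 3, 6], "rate")
        kh, _ = estimate_kdecay(c, [0, 3, 6], "halflife")
        assert kr == pytest.approx(kh, rel=1e-12)

    def test_missing_timepoint_dropped_not_fatal(self):
        k, n = estimate_kdecay([4.0, np.nan, 1.0], [0.0, 3.0, 6.0])
        assert n == 1
        assert k == pytest.approx(-np.log(1 / 4) / 6)

    def test_zero_c0_is_censored(self):
        k, n = estimate_kdecay([0.0, 1.0, 1.0], [0.0, 3.0, 6.0])
        assert np.isnan(k) and n == 0

    def test_unsorted_timepoints_handled(self):
        c = 3.0 * np.exp(-0.2 * np.array([6.0, 0.0, 3.0]))
        k, _ = estimate_kdecay(c, [6.0, 0.0, 3.0])
        assert k == pytest.approx(0.2)

    def test_requires_t_zero(self):
        with pytest.raises(ValidationError):
            estimate_kdecay([1.0, 0.5], [1.0, 2.0])


class TestHalfLife:
    def test_identity(self):
        assert half_life(LN2 / 4.0) == pytest.approx(4.0)
        assert half_life(0.0463) == pytest.approx(LN2 / 0.0463)

    @pytest.mark.parametrize("k", [0.0, -0.1, np.nan, np.inf])
    def test_nonpositive_or_nonfinite_censored(self, k):
        assert np.isnan(half_life(k))


class TestCalibration:
    def _decay_matrix(self, spike_counts, gene_counts=(100,)):
        n_g = len(gene_counts)
        idx = [f"gene{i}" for i in range(n_g)] + [f"ERCC-{i}" for i in range(len(spike_counts))]
        df = pd.DataFrame({"s1": list(gene_counts) + list(spike_counts)}, index=idx)
        from m6adecay.core_io import CountMatrix, SampleMeta

        return CountMatrix(df, [SampleMeta("s1", "control", "input", 0.0, 1)])

    def test_exact_linear_relation_recovered(self):
        # spike counts exactly proportional to amounts: slope 1, R^2 = 1,
        # and calibration inverts CPM back to attomole exactly
        amounts = pd.Series([1.0, 10.0, 100.0, 1000.0], index=[f"ERCC-{i}" for i in range(4)])
        ref = SpikeInReference(amounts)
        m = self._decay_matrix([10, 100, 1000, 10000], gene_counts=(50,))
        fits = fit_spikein_calibration(m, ref)
        f = fits["s1"]
        assert f.slope == pytest.approx(1.0)
        assert f.r_squared == pytest.approx(1.0)
        cpm_per_count = 1e6 / (50 + 11110)
        assert cpm_to_attomole(10 * cpm_per_count, f) == pytest.approx(1.0)
        assert cpm_to_attomole(10000 * cpm_per_count, f) == pytest.approx(1000.0)

    def test_depth_changes_intercept_not_slope(self):
        amounts = pd.Series([1.0, 10.0, 100.0], index=[f"ERCC-{i}" for i in range(3)])
        ref = SpikeInReference(amounts)
        a = self._decay_matrix([20, 200, 2000])
        b = self._decay_matrix([40, 400, 4000], gene_counts=(200,))
        fa = fit_spikein_calibration(a, ref)["s1"]
        fb = fit_spikein_calibration(b, ref)["s1"]
        assert fa.slope == pytest.approx(fb.slope)
        # same known amounts recovered from both libraries despite depth change
        cpm_a = 20 / (100 + 2220) * 1e6
        cpm_b = 40 / (200 + 4440) * 1e6
        assert cpm_to_attomole(cpm_a, fa) == pytest.approx(cpm_to_attomole(cpm_b, fb))

    def test_undetected_gene_maps_to_nan(self):
        f = CalibrationFit("s", 1.0, 0.0, 1.0, 3)
        assert np.isnan(cpm_to_attomole(0.0, f))

    def test_too_few_detected_spikes_errors(self):
        amounts = pd.Series([1.0, 10.0, 100.0], index=[f"ERCC-{i}" for i in range(3)])
        ref = SpikeInReference(amounts)
        m = self._decay_matrix([0, 0, 500])
        with pytest.raises(ValidationError, match="s1"):
            fit_spikein_calibration(m, ref)


class TestEstimateHalfLives:
    def test_noiseless_closed_loop_recovers_truth(self):
        """Simulator -> calibration -> kinetics returns the exact K and t1/2."""
        p = SimulationParams(seed=3, n_genes=80, n_spikes=12, depth_mean=1e6)
        gt = simulate_transcriptome(p)
        m, ref = simulate_decay_timecourse(gt, p, noiseless=True)
        hl = estimate_half_lives(m, ref)
        for cond in ("control", "patient"):
            sub = hl[hl.condition == cond].set_index("gene_id")
            k_true = gt[f"k_{cond}"]
            err = np.abs(sub.loc[k_true.index, "k_per_h"] - k_true) / k_true
            assert err.max() < 1e-9
            assert np.allclose(
                sub.loc[k_true.index, "halflife_h"], LN2 / k_true, rtol=1e-9
            )
            # absolute scale: recovered C0 matches ground-truth attomole
            assert np.allclose(sub.loc[k_true.index, "c0_attomole"], gt[f"c0_{cond}"], rtol=1e-6)

    def test_patient_targets_longer_half_life_noiseless(self):
        p = SimulationParams(seed=5, n_genes=100, n_spikes=12, depth_mean=1e6)
        gt = simulate_transcriptome(p)
        m, ref = simulate_decay_timecourse(gt, p, noiseless=True)
        hl = estimate_half_lives(m, ref)
        wide = hl.pivot(index="gene_id", columns="condition", values="halflife_h")
        slower = gt.is_hypo & gt.is_reader_target
        assert (wide.loc[slower, "patient"] > wide.loc[slower, "control"]).all()
        assert np.allclose(
            wide.loc[~slower, "patient"], wide.loc[~slower, "control"], rtol=1e-9
        )

    def test_noisy_estimates_unbiased_in_median(self, default_study, default_truth):
        hl = estimate_half_lives(default_study.decay, default_study.spikes)
        sub = hl[(hl.condition == "control") & ~hl.censored].set_index("gene_id")
        ratio = sub.halflife_h / (LN2 / default_truth.loc[sub.index, "k_control"])
        assert abs(np.log(ratio.median())) < 0.1

    def test_censored_flagged_not_dropped(self):
        p = SimulationParams(seed=3, n_genes=30, n_spikes=12, depth_mean=1e6)
        gt = simulate_transcriptome(p)
        m, ref = simulate_decay_timecourse(gt, p)
        hl = estimate_half_lives(m, ref)
        assert len(hl) == 2 * 30
        assert hl.censored.equals(~np.isfinite(hl.halflife_h))


class TestCompareGroups:
    def test_shift_detected_and_direction(self):
        rng = np.random.default_rng(0)
        a = rng.lognormal(np.log(8), 0.2, 40)  # longer half-lives
        b = rng.lognormal(np.log(5), 0.2, 40)
        res = compare_half_life_groups(a, b)
        assert res.p_value < 1e-6
        assert res.delta_median > 0

    def test_censored_counted_and_excluded(self):
        a = [5.0, 6.0, np.nan, 7.0]
        b = [5.5, 6.5, 6.0]
        res = compare_half_life_groups(a, b)
        assert res.n_a == 3 and res.n_censored_a == 1
        assert res.n_b == 3 and res.n_censored_b == 0

    def test_too_few_uncensored_errors(self):
        with pytest.raises(ValidationError):
            compare_half_life_groups([1.0, np.nan], [2.0, 3.0])
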