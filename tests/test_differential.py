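import math

import numpy as np
import pytest

from mitofoot import (
    CScoreTrack,
    GenomeSpec,
    Interval,
    ScanParams,
    ShuffleNull,
    build_shuffle_null,
    calibrate_fdr_threshold,
    compute_r_score,
    detect_differential_footprints,
    estimate_fdr,
    evaluate_locus,
    simulate_experiment,
    summarize_r_change,
    SimulationSpec,
)
from mitofoot.footprint_detection import Footprint

from conftest import make_profile


def ctrack(values, name="chrM"):
    values = np.asarray(values, float)
    return CScoreTrack(GenomeSpec(name, len(values), circular=True), "+", values)


def fp_at(genome, start, end):
    return Footprint(genome, "+", start, end, 0.0, 0.0, 0.0, 0.0)


class TestEvaluateLocus:
    def test_identical_tracks_give_zero_fold_change(self):
        rng = np.random.default_rng(0)
        cs = ctrack(rng.normal(0, 1, 200))
        rec = evaluate_locus(fp_at(cs.genome, 50, 70), cs, cs)
        assert rec.log2fc == 0.0
        assert rec.f_control == rec.f_experiment

    def test_hand_constructed_fold_change(self):
        # locus [20, 30): control centre 1 log10 unit below flanks -> F_a = 0.2;
        # experiment centre ~0.4 log10 above a baseline tuned so F_b = 0.8
        a = np.zeros(200)
        a[20:30] = -1.0
        b = np.zeros(200)
        b[20:30] = -math.log10(2.5)  # 10^C/10^L * 2 = 2 * 10^(-log10 2.5) = 0.8
        rec = evaluate_locus(fp_at(ctrack(a).genome, 20, 30), ctrack(a), ctrack(b))
        assert rec.f_control == pytest.approx(0.2)
        assert rec.f_experiment == pytest.approx(0.8)
        assert rec.log2fc == pytest.approx(2.0)

    def test_swapping_tracks_negates_fold_change(self):
        rng = np.random.default_rng(1)
        cs_a, cs_b = ctrack(rng.normal(0, 1, 200)), ctrack(rng.normal(0, 1, 200))
        fp = fp_at(cs_a.genome, 100, 120)
        fwd = evaluate_locus(fp, cs_a, cs_b)
        rev = evaluate_locus(fp, cs_b, cs_a)
        assert fwd.log2fc == pytest.approx(-rev.log2fc)

    def test_out_of_range_coordinates_rejected(self):
        cs = ctrack(np.zeros(200))
        with pytest.raises(ValueError):
            evaluate_locus(fp_at(cs.genome, 300, 320), cs, cs)


class TestShuffleNull:
    def test_constant_tracks_give_all_zero_null(self):
        cs = ctrack(np.full(200, 0.5))
        loci = [fp_at(cs.genome, 10, 30), fp_at(cs.genome, 100, 115)]
        null = build_shuffle_null(cs, cs, loci, n_shuffles=5, seed=3)
        assert null.null_log2fc.shape == (2, 5)
        np.testing.assert_allclose(null.null_log2fc, 0.0, atol=1e-12)

    def test_fixed_seed_is_reproducible(self):
        rng = np.random.default_rng(4)
        cs_a, cs_b = ctrack(rng.normal(0, 1, 300)), ctrack(rng.normal(0, 1, 300))
        loci = [fp_at(cs_a.genome, 40, 60)]
        n1 = build_shuffle_null(cs_a, cs_b, loci, n_shuffles=1, seed=99)
        n2 = build_shuffle_null(cs_a, cs_b, loci, n_shuffles=1, seed=99)
        np.testing.assert_array_equal(n1.null_log2fc, n2.null_log2fc)

    def test_empty_loci_list_gives_empty_null(self):
        cs = ctrack(np.zeros(200))
        null = build_shuffle_null(cs, cs, [], n_shuffles=10, seed=0)
        assert null.null_log2fc.shape[0] == 0

    def test_null_symmetric_about_zero_for_exchangeable_tracks(self):
        # swapping the two samples' labels negates the null fold changes, so
        # for tracks drawn from the same distribution the null distribution
        # is symmetric about 0 up to Monte-Carlo error
        rng = np.random.default_rng(5)
        cs_a, cs_b = ctrack(rng.normal(0, 1, 400)), ctrack(rng.normal(0, 1, 400))
        loci = [fp_at(cs_a.genome, 100, 120), fp_at(cs_a.genome, 250, 270)]
        null = build_shuffle_null(cs_a, cs_b, loci, n_shuffles=1000, seed=6)
        vals = null.null_log2fc.ravel()
        assert abs(np.mean(vals)) < 3 * np.std(vals) / math.sqrt(vals.size)
        # swapping the sample labels flips the sign of the distribution
        swapped = build_shuffle_null(cs_b, cs_a, loci, n_shuffles=1000, seed=6)
        sv = swapped.null_log2fc.ravel()
        se = np.std(vals) / math.sqrt(vals.size) + np.std(sv) / math.sqrt(sv.size)
        assert abs(np.mean(sv) + np.mean(vals)) < 3 * se


class TestFdrCalibration:
    def test_ratio_estimator_hand_value(self):
        # 2 observed values beyond t=2; null has one exceedance over 10
        # shuffles -> mean null count 0.1 -> FDR(2) = 0.1 / 2 = 0.05
        observed = [3.0, 3.0, 0.1]
        null_vals = np.zeros((3, 10))
        null_vals[0, 0] = 2.5
        null = ShuffleNull(10, 0, null_vals)
        assert estimate_fdr(observed, null, 2.0, "up") == pytest.approx(0.05)

    def test_perfect_separation_calls_everything(self):
        observed = [10.0, 10.0, 10.0]
        null = ShuffleNull(4, 0, np.zeros((3, 4)))
        t = calibrate_fdr_threshold(observed, null, 0.05, "up")
        assert t < 10.0
        assert all(v > t for v in observed)

    def test_permissive_target_threshold_below_smallest_observed(self):
        rng = np.random.default_rng(7)
        observed = rng.uniform(1, 2, 10)
        null = ShuffleNull(5, 0, rng.normal(0, 0.5, (10, 5)))
        t = calibrate_fdr_threshold(observed, null, 0.999, "up")
        assert t < observed.min()

    def test_unattainable_target_returns_infinity(self):
        observed = [0.1]
        null = ShuffleNull(2, 0, np.full((1, 2), 5.0))  # null dominates
        assert calibrate_fdr_threshold(observed, null, 0.01, "up") == math.inf
        assert calibrate_fdr_threshold([-0.1], ShuffleNull(2, 0, np.full((1, 2), -5.0)),
                                       0.01, "down") == -math.inf

    def test_down_direction_mirrors_up(self):
        rng = np.random.default_rng(8)
        observed = rng.normal(2, 0.1, 20)
        null_vals = rng.normal(0, 0.5, (20, 50))
        up = calibrate_fdr_threshold(observed, ShuffleNull(50, 0, null_vals), 0.05, "up")
        down = calibrate_fdr_threshold(-observed, ShuffleNull(50, 0, -null_vals), 0.05, "down")
        assert down == pytest.approx(-up)

    def test_empty_observed_rejected(self):
        with pytest.raises(ValueError):
            calibrate_fdr_threshold([], ShuffleNull(2, 0, np.zeros((1, 2))), 0.05, "up")


class TestDetectDifferential:
    def test_identical_profiles_yield_no_significant_loci(self):
        spec = SimulationSpec(genome_length=2000, n_protected=2,
                              protected_width_range=(20, 20), seed=10)
        ctrl, _, _ = simulate_experiment(spec)
        calls = detect_differential_footprints(ctrl, ctrl, n_shuffles=20, seed=1)
        assert len(calls.significant) == 0

    def test_planted_protection_detected_control_defined(self):
        spec = SimulationSpec(genome_length=4000, n_protected=3,
                              protected_width_range=(20, 20),
                              protection_factor=8, base_rate=100, seed=11)
        ctrl, ko, truth = simulate_experiment(spec)
        calls = detect_differential_footprints(
            ctrl, ko, direction="control_defined", n_shuffles=200, seed=12
        )
        sig = calls.significant
        assert sig and all(r.log2fc > 0 for r in sig)
        for iv in truth.protected:
            assert any(
                r.footprint.start < iv.end and iv.start < r.footprint.end for r in sig
            ), f"planted protection {iv.start}-{iv.end} missed"

    def test_planted_protection_not_reported_knockout_defined(self):
        spec = SimulationSpec(genome_length=4000, n_protected=3,
                              protected_width_range=(20, 20),
                              protection_factor=8, base_rate=100, seed=11)
        ctrl, ko, truth = simulate_experiment(spec)
        calls = detect_differential_footprints(
            ctrl, ko, direction="knockout_defined", n_shuffles=200, seed=12
        )
        for iv in truth.protected:
            assert not any(
                r.footprint.start < iv.end and iv.start < r.footprint.end
                for r in calls.significant
            )

    def test_knockout_defined_significant_calls_are_negative(self):
        # swap genotypes so protection is present in the "knockout" sample
        spec = SimulationSpec(genome_length=4000, n_protected=3,
                              protected_width_range=(20, 20),
                              protection_factor=8, base_rate=100, seed=13)
        ctrl, ko, _ = simulate_experiment(spec)
        calls = detect_differential_footprints(
            ko, ctrl, direction="knockout_defined", n_shuffles=200, seed=14
        )
        assert calls.significant
        assert all(r.log2fc < 0 for r in calls.significant)

    def test_determinism_for_fixed_seed(self):
        spec = SimulationSpec(genome_length=2000, n_protected=2,
                              protected_width_range=(20, 20), seed=15)
        ctrl, ko, _ = simulate_experiment(spec)
        a = detect_differential_footprints(ctrl, ko, n_shuffles=50, seed=5)
        b = detect_differential_footprints(ctrl, ko, n_shuffles=50, seed=5)
        assert [(r.footprint.start, r.log2fc, r.significant) for r in a] == [
            (r.footprint.start, r.log2fc, r.significant) for r in b
        ]
        assert a.threshold == b.threshold


class TestRChangeSummary:
    def _tracks(self, genome, a_ko, a_wt):
        r_ko = compute_r_score(make_profile(genome, a=a_ko))
        r_wt = compute_r_score(make_profile(genome, a=a_wt))
        return r_ko, r_wt

    def test_identical_r_tracks_give_zero_summary(self, genome100):
        a = np.full(100, 10.0)
        r_ko, r_wt = self._tracks(genome100, a, a.copy())
        fps = [fp_at(genome100, 20, 40)]
        sites = [Interval(genome100, 25, 35)]
        summary = summarize_r_change(fps, r_ko, r_wt, sites)
        assert summary.central == pytest.approx([0.0])
        assert summary.left_flank == pytest.approx([0.0])

    def test_footprint_without_site_overlap_excluded(self, genome100):
        a = np.full(100, 10.0)
        r_ko, r_wt = self._tracks(genome100, a, a.copy())
        fps = [fp_at(genome100, 20, 40), fp_at(genome100, 60, 80)]
        sites = [Interval(genome100, 39, 45)]  # 1 nt overlap with the first only
        summary = summarize_r_change(fps, r_ko, r_wt, sites)
        assert len(summary) == 1

    def test_planted_structure_gain_raises_central_median(self):
        genome = GenomeSpec("chrM", 1000)
        rng = np.random.default_rng(20)
        a_wt = rng.poisson(50, 1000).astype(float)
        a_ko = a_wt.copy()
        fps, sites = [], []
        for s in range(100, 900, 200):
            a_ko[s : s + 20] *= 4  # structure gained in knockout inside footprints
            fps.append(fp_at(genome, s - 1, s + 19))  # score reads i+1
            sites.append(Interval(genome, s, s + 20))
        r_ko, r_wt = self._tracks(genome, a_ko, a_wt)
        summary = summarize_r_change(fps, r_ko, r_wt, sites)
        med = summary.medians()
        assert med["central"] > med["left_flank"]
        assert med["central"] > med["right_flank"]
        assert med["central"] > 0
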