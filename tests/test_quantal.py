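"""Amplitude extraction, CV quantal analysis and exact Wilcoxon tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from triokit.quantal import (
    AMBIGUOUS,
    QUANTAL_CONTENT,
    QUANTAL_SIZE,
    PairedRecording,
    SweepTrain,
    classify_cv_point,
    cv_inverse_squared,
    cv_pair_analysis,
    extract_amplitude,
    ppf_ratio,
    qc_series_resistance,
    rank_sum,
    simulate_quantal_pairs,
    wilcoxon_signed_rank,
)
from triokit.synthetic import generate_epsc_trace


class TestAmplitudeExtraction:
    def test_ampar_peak_recovered_from_synthetic_epsc(self):
        t, i = generate_epsc_trace(50.0, receptor="AMPAR", noise_sd_pa=0.2, seed=1)
        amp = extract_amplitude(t, i, stim_time_s=0.05, receptor="AMPAR")
        assert amp == pytest.approx(50.0, abs=1.0)

    def test_flat_trace_gives_zero(self):
        t = np.linspace(0, 0.3, 3000)
        amp = extract_amplitude(t, np.zeros_like(t), 0.05, "AMPAR")
        assert amp == 0.0

    def test_nmdar_value_at_isolation_point(self):
        t = np.linspace(0, 0.3, 3000)
        i = np.where(t >= 0.05, -30.0, 0.0)
        amp = extract_amplitude(t, i, 0.05, "NMDAR")
        assert amp == pytest.approx(30.0, abs=1e-9)

    def test_nmdar_uses_late_point_not_peak(self):
        t, i = generate_epsc_trace(40.0, receptor="NMDAR", seed=0)
        amp = extract_amplitude(t, i, stim_time_s=0.05, receptor="NMDAR")
        assert 0 < amp < 40.0  # decayed below peak 150 ms after the stimulus

    def test_window_outside_trace_rejected(self):
        t = np.linspace(0, 0.1, 1000)
        with pytest.raises(ValueError):
            extract_amplitude(t, np.zeros_like(t), 0.05, "NMDAR")


class TestSeriesResistanceQc:
    def test_thirty_percent_drift_discarded(self):
        train = SweepTrain([10.0, 11.0], series_resistance_mohm=[10.0, 13.0])
        assert qc_series_resistance(train) is False

    def test_twenty_percent_drift_kept(self):
        train = SweepTrain([10.0, 11.0], series_resistance_mohm=[10.0, 12.0])
        assert qc_series_resistance(train) is True

    def test_constant_readings_kept(self):
        train = SweepTrain([10.0, 11.0], series_resistance_mohm=[12.0, 12.0, 12.0])
        assert qc_series_resistance(train) is True

    def test_missing_readings_warn_and_pass(self):
        train = SweepTrain([10.0, 11.0])
        with pytest.warns(UserWarning):
            assert qc_series_resistance(train) is True


class TestPpf:
    def test_ratio_arithmetic(self):
        assert ppf_ratio(20.0, 30.0) == pytest.approx(1.5)
        assert ppf_ratio(7.3, 7.3) == pytest.approx(1.0)

    def test_unit_invariance(self):
        assert ppf_ratio(20.0, 30.0) == ppf_ratio(2.0, 3.0)

    def test_zero_first_peak_rejected(self):
        with pytest.raises(ValueError):
            ppf_ratio(0.0, 10.0)

    def test_simulated_facilitating_synapse(self):
        # Second pulse raises release probability 0.25 -> 0.35 (PPF 1.4).
        rng = np.random.default_rng(8)
        n, N, q = 4000, 120, 8.0
        peak1 = q * rng.binomial(N, 0.25, n)
        peak2 = q * rng.binomial(N, 0.35, n)
        assert ppf_ratio(peak1.mean(), peak2.mean()) == pytest.approx(1.4, abs=0.02)


class TestCvInverseSquared:
    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cv_inverse_squared(SweepTrain([5.0, 5.0, 5.0]))

    def test_binomial_closed_form(self):
        pair = simulate_quantal_pairs(
            n_sites=100, release_p=0.3, quantal_cv=0.0, n_sweeps=10_000, seed=12
        )
        expected = 100 * 0.3 / 0.7  # Np/(1-p)
        assert cv_inverse_squared(pair.control) == pytest.approx(expected, rel=0.05)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        amps = rng.gamma(5.0, 2.0, size=200)
        a = cv_inverse_squared(SweepTrain(amps))
        b = cv_inverse_squared(SweepTrain(17.3 * amps))
        assert a == pytest.approx(b, rel=1e-12)

    def test_noise_variance_subtraction(self):
        amps = np.array([8.0, 12.0, 9.0, 11.0, 10.0, 10.0])
        raw = cv_inverse_squared(SweepTrain(amps))
        corrected = cv_inverse_squared(SweepTrain(amps), noise_variance=0.5)
        assert corrected > raw
        with pytest.raises(ValueError):
            cv_inverse_squared(SweepTrain(amps), noise_variance=1e3)


class TestCvPairAnalysis:
    def test_quantal_size_manipulation_on_horizontal_line(self):
        pair = simulate_quantal_pairs(
            manipulation="scale_q", factor=0.5, n_sweeps=20_000, quantal_cv=0.0, seed=5
        )
        summaries, centroid = cv_pair_analysis([pair])
        assert summaries[0].mean_ratio == pytest.approx(0.5, abs=0.02)
        assert summaries[0].cv_inv_sq_ratio == pytest.approx(1.0, abs=0.1)
        assert centroid["classification"] == QUANTAL_SIZE

    def test_quantal_content_manipulation_on_diagonal(self):
        pair = simulate_quantal_pairs(
            manipulation="scale_N", factor=0.5, n_sweeps=20_000, quantal_cv=0.0, seed=6
        )
        summaries, _ = cv_pair_analysis([pair])
        assert summaries[0].mean_ratio == pytest.approx(0.5, abs=0.02)
        assert summaries[0].cv_inv_sq_ratio == pytest.approx(0.5, abs=0.07)
        assert summaries[0].classification == QUANTAL_CONTENT

    def test_identical_trains_are_ambiguous(self):
        train = SweepTrain(np.array([10.0, 12.0, 9.0, 11.0, 13.0]))
        pair = PairedRecording(control=train, transfected=train)
        summaries, centroid = cv_pair_analysis([pair])
        assert summaries[0].mean_ratio == 1.0
        assert summaries[0].cv_inv_sq_ratio == 1.0
        assert summaries[0].classification == AMBIGUOUS
        assert centroid["n_pairs"] == 1

    def test_degenerate_pair_skipped_with_warning(self):
        good = simulate_quantal_pairs(n_sweeps=100, seed=3)
        flat = SweepTrain(np.array([5.0, 5.0, 5.0]))
        bad = PairedRecording(control=flat, transfected=flat, pair_id="flat")
        with pytest.warns(UserWarning):
            summaries, centroid = cv_pair_analysis([good, bad])
        assert len(summaries) == 1

    def test_classifier_geometry(self):
        assert classify_cv_point(0.5, 1.0) == QUANTAL_SIZE
        assert classify_cv_point(0.5, 0.5) == QUANTAL_CONTENT
        assert classify_cv_point(2.0, 2.0) == QUANTAL_CONTENT
        assert classify_cv_point(1.0, 1.0) == AMBIGUOUS
        with pytest.raises(ValueError):
            classify_cv_point(-1.0, 1.0)


def brute_force_signed_rank_p(diffs):
    """Independent oracle: enumerate all 2^n sign assignments."""
    diffs = np.asarray(diffs, float)
    diffs = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(diffs))
    observed = ranks[diffs > 0].sum()
    sums = [
        np.sum(ranks[np.array(signs, dtype=bool)])
        for signs in itertools.product([0, 1], repeat=diffs.size)
    ]
    sums = np.array(sums)
    p_le = np.mean(sums <= observed + 1e-9)
    p_ge = np.mean(sums >= observed - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


def brute_force_rank_sum_p(a, b):
    """Independent oracle: enumerate all C(n+m, n) group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    observed = ranks[: a.size].sum()
    sums = np.array(
        [sum(ranks[list(idx)]) for idx in itertools.combinations(range(combined.size), a.size)]
    )
    p_le = np.mean(sums <= observed + 1e-9)
    p_ge = np.mean(sums >= observed - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxonSignedRank:
    def test_seven_one_signed_differences(self):
        p = wilcoxon_signed_rank([1.0, 2.0, 0.5, 3.0, 1.5, 2.5, 0.7])
        assert p == pytest.approx(2 / 2**7)  # 0.015625 < 0.05

    def test_five_one_signed_differences(self):
        p = wilcoxon_signed_rank([1.0, 2.0, 0.5, 3.0, 1.5])
        assert p == pytest.approx(2 / 2**5)  # 0.0625 > 0.05

    def test_antisymmetric_pair(self):
        assert wilcoxon_signed_rank([1.0, -1.0]) == pytest.approx(1.0)

    def test_all_zero_differences_undefined(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    @pytest.mark.parametrize("n", range(3, 11))
    def test_matches_exhaustive_enumeration(self, n):
        rng = np.random.default_rng(100 + n)
        diffs = np.round(rng.standard_normal(n), 1)  # rounding induces ties
        diffs[diffs == 0] = 0.1
        assert wilcoxon_signed_rank(diffs) == pytest.approx(
            brute_force_signed_rank_p(diffs), abs=1e-12
        )

    def test_paired_interface_matches_difference_interface(self):
        x = [12.0, 15.0, 9.0, 20.0]
        y = [10.0, 11.0, 9.5, 14.0]
        d = np.subtract(x, y)
        assert wilcoxon_signed_rank(x, y) == wilcoxon_signed_rank(d)

    def test_cross_check_scipy_exact_no_ties(self):
        rng = np.random.default_rng(17)
        d = rng.standard_normal(12)
        ours = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, mode="exact", alternative="two-sided").pvalue
        assert ours == pytest.approx(float(ref), abs=1e-9)

    def test_large_sample_normal_approximation_is_sane(self):
        rng = np.random.default_rng(23)
        d = rng.standard_normal(60) + 0.8
        p = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, correction=True, alternative="two-sided").pvalue
        assert p == pytest.approx(float(ref), rel=0.1)


class TestRankSum:
    def test_fully_separated_small_groups(self):
        assert rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_near_one(self):
        assert rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) >= 0.6

    def test_single_extreme_observation(self):
        p = rank_sum([100.0], [1.0, 2.0, 3.0, 4.0, 5.0])
        assert p == pytest.approx(2 / 6)  # bounded below by exact enumeration

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([], [1.0])

    @pytest.mark.parametrize("n,m", [(3, 3), (4, 5), (5, 5), (2, 8)])
    def test_matches_exhaustive_enumeration(self, n, m):
        rng = np.random.default_rng(n * 31 + m)
        a = np.round(rng.standard_normal(n), 1)
        b = np.round(rng.standard_normal(m) + 0.4, 1)
        assert rank_sum(a, b) == pytest.approx(brute_force_rank_sum_p(a, b), abs=1e-12)

    def test_large_sample_cross_check_scipy(self):
        rng = np.random.default_rng(41)
        a = rng.standard_normal(30)
        b = rng.standard_normal(25) + 0.6
        p = rank_sum(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(float(ref), rel=0.1)


class TestSimulator:
    def test_reproducible_under_seed(self):
        a = simulate_quantal_pairs(seed=99)
        b = simulate_quantal_pairs(seed=99)
        assert np.array_equal(a.control.amplitudes, b.control.amplitudes)
        assert np.array_equal(a.transfected.amplitudes, b.transfected.amplitudes)

    def test_mean_matches_npq(self):
        pair = simulate_quantal_pairs(
            n_sites=100, release_p=0.3, quantal_size=10.0, quantal_cv=0.0,
            n_sweeps=10_000, seed=4,
        )
        mean = pair.control.mean
        se = math.sqrt(pair.control.variance / pair.control.n_sweeps)
        assert abs(mean - 300.0) < 3 * se

    def test_scale_q_scales_mean_not_cv(self):
        pair = simulate_quantal_pairs(
            manipulation="scale_q", factor=0.6, quantal_cv=0.0, n_sweeps=20_000, seed=10
        )
        ratio = pair.transfected.mean / pair.control.mean
        assert ratio == pytest.approx(0.6, abs=0.02)

    def test_scale_n_halves_cv_inverse_squared(self):
        pair = simulate_quantal_pairs(
            manipulation="scale_N", factor=0.5, quantal_cv=0.0, n_sweeps=20_000, seed=11
        )
        r = cv_inverse_squared(pair.transfected) / cv_inverse_squared(pair.control)
        assert r == pytest.approx(0.5, abs=0.07)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_quantal_pairs(release_p=1.5)
        with pytest.raises(ValueError):
            simulate_quantal_pairs(manipulation="scale_tau")
        with pytest.raises(ValueError):
            simulate_quantal_pairs(factor=-1.0)
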