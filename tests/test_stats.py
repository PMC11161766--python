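import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasecode.stats import (circular_mean_difference,
                             combine_pvalues_product, demean_responses,
                             fit_fixed_frequency_sinusoid,
                             logistic_phase_regression,
                             permutation_sinusoid_test,
                             split_half_comparison, v_test,
                             validate_response_table)
from phasecode.synth import BehavioralSimSpec, generate_behavioral_dataset

SOAS = np.linspace(0.1, 0.42, 12)
F = 6.25


def table_from_matrix(mat, soas=SOAS):
    """Build a trial table whose per-cell proportions equal ``mat`` exactly."""
    rows = []
    denom = 20
    for i, row in enumerate(mat):
        for soa, p in zip(soas, row):
            k = int(round(p * denom))
            for j in range(denom):
                rows.append((f"p{i:02d}", float(soa), "m", int(j < k),
                             1 if j % 2 == 0 else 2))
    return pd.DataFrame(rows, columns=["participant", "soa_s", "morph",
                                       "response", "half"])


class TestResponseTableValidation:
    def test_millisecond_soas_rejected(self):
        tab = pd.DataFrame({"participant": ["a"], "soa_s": [100.0],
                            "morph": ["m"], "response": [1]})
        with pytest.raises(ValueError, match="milliseconds"):
            validate_response_table(tab)

    def test_nonbinary_responses_rejected(self):
        tab = pd.DataFrame({"participant": ["a"], "soa_s": [0.1],
                            "morph": ["m"], "response": [2]})
        with pytest.raises(ValueError):
            validate_response_table(tab)

    def test_condition_column_required(self):
        tab = pd.DataFrame({"participant": ["a"], "morph": ["m"],
                            "response": [1]})
        with pytest.raises(ValueError):
            validate_response_table(tab)

    def test_missing_cells_detected(self):
        tab = pd.DataFrame({
            "participant": ["a", "a", "b"], "soa_s": [0.1, 0.2, 0.1],
            "morph": "m", "response": [1, 0, 1]})
        with pytest.raises(ValueError, match="missing"):
            demean_responses(tab)


class TestDemeaning:
    def test_constant_participant_becomes_zero(self):
        mat = np.full((3, 12), 0.65)
        _, dem, group = demean_responses(table_from_matrix(mat))
        assert np.allclose(dem, 0.0)
        assert np.allclose(group, 0.0)

    def test_invariant_to_participant_offsets(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.3, 0.6, (4, 12)).round(2)
        shifted = (base + np.array([[0.05], [-0.05], [0.1], [0.0]])).round(2)
        _, dem1, _ = demean_responses(table_from_matrix(base))
        _, dem2, _ = demean_responses(table_from_matrix(shifted))
        assert np.allclose(dem1, dem2, atol=1e-12)

    def test_opposite_sinusoids_cancel(self):
        s = 0.2 * np.sin(2 * np.pi * F * SOAS)
        mat = np.round(np.stack([0.5 + s, 0.5 - s]), 2)
        _, _, group = demean_responses(table_from_matrix(mat))
        assert np.abs(group).max() < 0.03  # rounding to 1/20 grid


class TestSinusoidFit:
    def test_exact_sinusoid(self):
        y = 0.2 * np.sin(2 * np.pi * F * SOAS)
        fit = fit_fixed_frequency_sinusoid(y, SOAS, F)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.amplitude == pytest.approx(0.2)
        # phase convention atan2(sin_coef, cos_coef): pi/2 for a pure sine
        assert fit.phase == pytest.approx(np.pi / 2, abs=1e-9)

    def test_orthogonal_signal_gives_zero_r2(self):
        x = _centered_design(SOAS, F)
        y = np.random.default_rng(1).standard_normal(12)
        y = y - y.mean()
        y -= x @ np.linalg.lstsq(x, y, rcond=None)[0]
        fit = fit_fixed_frequency_sinusoid(y, SOAS, F)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_flagged(self):
        fit = fit_fixed_frequency_sinusoid(np.zeros(12), SOAS, F)
        assert fit.degenerate
        assert np.isnan(fit.r_squared)

    def test_phase_recovery_under_noise(self):
        # median error over 100 noisy draws stays within 0.3 rad
        rng = np.random.default_rng(2)
        errors = []
        for _ in range(100):
            phi = rng.uniform(-np.pi, np.pi)
            y = 0.2 * np.sin(2 * np.pi * F * SOAS + phi)
            y = y + rng.normal(0, 0.05, 12)
            fit = fit_fixed_frequency_sinusoid(y - y.mean(), SOAS, F)
            # A sin(arg + phi) has a = A cos(phi), b = A sin(phi), so the
            # sine offset is pi/2 - atan2(a, b)
            recovered = np.pi / 2 - fit.phase
            errors.append(abs(np.angle(np.exp(1j * (recovered - phi)))))
        assert np.median(errors) < 0.3

    def test_pipeline_r2_invariant_to_constant_shift(self):
        rng = np.random.default_rng(3)
        mat = rng.uniform(0.3, 0.7, (5, 12)).round(2)
        for shift in (0.0, 0.1):
            _, _, group = demean_responses(table_from_matrix(
                np.round(mat + shift, 2)))
            fit = fit_fixed_frequency_sinusoid(group, SOAS, F)
            if shift == 0.0:
                base = fit.r_squared
        assert fit.r_squared == pytest.approx(base, abs=1e-12)


def _centered_design(soas, f):
    arg = 2 * np.pi * f * soas
    x = np.column_stack([np.sin(arg), np.cos(arg)])
    return x - x.mean(axis=0)


class TestPermutationTest:
    def test_seeded_reproducibility(self):
        tab = generate_behavioral_dataset(BehavioralSimSpec(seed=4))
        p1 = permutation_sinusoid_test(tab, F, n_perm=300, seed=7).p
        p2 = permutation_sinusoid_test(tab, F, n_perm=300, seed=7).p
        assert p1 == p2

    def test_add_one_rule_bounds(self):
        tab = generate_behavioral_dataset(
            BehavioralSimSpec(modulation_amplitude=0.25, seed=5))
        res = permutation_sinusoid_test(tab, F, n_perm=200, seed=1)
        assert 0.0 < res.p <= 1.0
        assert res.p >= 1.0 / 201.0

    def test_detects_strong_modulation(self):
        tab = generate_behavioral_dataset(
            BehavioralSimSpec(modulation_amplitude=0.2, seed=6))
        assert permutation_sinusoid_test(tab, F, n_perm=500, seed=2).p < 0.01

    def test_null_pvalues_near_uniform(self):
        # Kolmogorov distance of null p-values from uniform
        from scipy.stats import kstest

        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            tab = generate_behavioral_dataset(BehavioralSimSpec(
                modulation_amplitude=0.0, n_participants=8,
                n_trials_per_soa=20, seed=int(rng.integers(2 ** 31))))
            ps.append(permutation_sinusoid_test(
                tab, F, n_perm=200, seed=int(rng.integers(2 ** 31))).p)
        assert kstest(ps, "uniform").statistic < 0.1

    def test_too_few_permutations_rejected(self):
        tab = generate_behavioral_dataset(BehavioralSimSpec(seed=4))
        with pytest.raises(ValueError):
            permutation_sinusoid_test(tab, F, n_perm=50)


class TestSplitHalf:
    def test_identical_halves_give_zero(self):
        mat = np.random.default_rng(0).uniform(0.3, 0.7, (4, 12)).round(2)
        half1 = table_from_matrix(mat).assign(half=1)
        tab = pd.concat([half1, half1.assign(half=2)], ignore_index=True)
        res = split_half_comparison(tab, F, n_perm=100, seed=1)
        assert res.observed == pytest.approx(0.0, abs=1e-12)

    def test_first_half_modulation_detected(self):
        tab = generate_behavioral_dataset(BehavioralSimSpec(
            modulation_amplitude=0.25, amplitude_second_half=0.0, seed=2))
        res = split_half_comparison(tab, F, n_perm=300, seed=3)
        assert res.observed > 0
        assert res.p < 0.05

    def test_seeded_reproducibility(self):
        tab = generate_behavioral_dataset(BehavioralSimSpec(seed=8))
        r1 = split_half_comparison(tab, F, n_perm=200, seed=5)
        r2 = split_half_comparison(tab, F, n_perm=200, seed=5)
        assert r1.observed == r2.observed and r1.p == r2.p

    def test_table_without_halves_rejected(self):
        tab = generate_behavioral_dataset(BehavioralSimSpec(seed=8))
        with pytest.raises(ValueError):
            split_half_comparison(tab.drop(columns=["half"]), F)


class TestLogisticPhaseRegression:
    def test_null_effect_magnitude_small(self):
        rng = np.random.default_rng(1)
        mags = []
        for _ in range(20):
            ph = rng.uniform(-np.pi, np.pi, 1000)
            y = (rng.random(1000) < 0.5).astype(float)
            mags.append(logistic_phase_regression(ph, y).effect_magnitude)
        assert np.median(mags) < 0.2

    def test_preferred_phase_recovery(self):
        rng = np.random.default_rng(2)
        errs = []
        for _ in range(20):
            phi0 = rng.uniform(-np.pi, np.pi)
            ph = rng.uniform(-np.pi, np.pi, 500)
            p = 1 / (1 + np.exp(-1.0 * np.cos(ph - phi0)))
            y = (rng.random(500) < p).astype(float)
            fit = logistic_phase_regression(ph, y)
            errs.append(abs(np.angle(np.exp(1j * (fit.preferred_phase
                                                  - phi0)))))
        assert np.median(errs) < np.pi / 8

    def test_relabeling_flips_preferred_phase(self):
        rng = np.random.default_rng(3)
        ph = rng.uniform(-np.pi, np.pi, 400)
        p = 1 / (1 + np.exp(-1.5 * np.cos(ph - 0.7)))
        y = (rng.random(400) < p).astype(float)
        f1 = logistic_phase_regression(ph, y)
        f2 = logistic_phase_regression(ph, 1.0 - y)
        flip = np.angle(np.exp(1j * (f1.preferred_phase
                                     - f2.preferred_phase)))
        assert abs(abs(flip) - np.pi) < 0.15

    def test_perfect_separation_flagged_and_capped(self):
        ph = np.linspace(-np.pi, np.pi, 100, endpoint=False)
        y = (np.cos(ph) > 0).astype(float)
        fit = logistic_phase_regression(ph, y)
        assert fit.separation
        assert abs(fit.beta_cos) <= 10.0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            logistic_phase_regression(np.zeros(10), np.ones(10))
        with pytest.raises(ValueError):
            logistic_phase_regression(np.zeros(30), np.ones(30))


class TestCircularMeanDifference:
    def test_identical_sets(self):
        ph = np.array([0.2, 0.5, -1.0])
        assert circular_mean_difference(ph, ph) == 0.0

    def test_wrapped_boundary(self):
        # means exactly pi apart wrap to -pi under the [-pi, pi) convention
        assert circular_mean_difference(np.array([0.0]),
                                        np.array([np.pi])) == -np.pi

    def test_von_mises_recovery(self):
        rng = np.random.default_rng(4)
        a = rng.vonmises(0.8, 20, 100)
        b = rng.vonmises(-0.4, 20, 100)
        assert abs(circular_mean_difference(a, b) - 1.2) < 0.1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            circular_mean_difference(np.array([]), np.array([0.0]))


def vtest_bruteforce(phases, mu):
    """Independent textbook formulation from the component sums."""
    phases = np.asarray(phases)
    n = len(phases)
    cbar = np.mean(np.cos(phases))
    sbar = np.mean(np.sin(phases))
    # projection of the mean resultant vector onto the direction mu
    return n * (cbar * np.cos(mu) + sbar * np.sin(mu))


class TestVTest:
    def test_all_phases_at_mu(self):
        res = v_test(np.full(10, 0.7), 0.7)
        assert res.v == pytest.approx(10.0)
        assert res.resultant_length == pytest.approx(1.0)

    def test_uniform_grid_gives_zero(self):
        ph = np.linspace(-np.pi, np.pi, 8, endpoint=False)
        assert v_test(ph, 0.3).v == pytest.approx(0.0, abs=1e-12)

    def test_normal_approximation_pvalue(self):
        from scipy.stats import norm

        res = v_test(np.zeros(10), 0.0)
        assert res.u == pytest.approx(np.sqrt(20.0))
        assert res.p == pytest.approx(1 - norm.cdf(np.sqrt(20.0)))

    def test_agrees_with_bruteforce(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            ph = rng.uniform(-np.pi, np.pi, n)
            mu = rng.uniform(-np.pi, np.pi)
            assert abs(v_test(ph, mu).v
                       - vtest_bruteforce(ph, mu)) < 1e-10

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            v_test(np.zeros(4), 0.0)


class TestCombinePValues:
    def test_reported_combination(self):
        assert combine_pvalues_product(
            [0.004, 0.019, 0.001]) == pytest.approx(7.6e-8)
        assert combine_pvalues_product([0.004, 0.019, 0.001]) < 0.001

    def test_trivial_cases(self):
        assert combine_pvalues_product([1.0, 1.0]) == 1.0
        assert combine_pvalues_product([0.3]) == 0.3

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            combine_pvalues_product([])
        with pytest.raises(ValueError):
            combine_pvalues_product([0.0, 0.5])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(-np.pi, np.pi - 1e-9), min_size=5, max_size=30),
       st.floats(-np.pi, np.pi))
def test_v_test_bounded_by_n(phases, mu):
    res = v_test(np.array(phases), mu)
    assert res.v <= res.n + 1e-9
    assert 0.0 <= res.resultant_length <= 1.0 + 1e-12
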