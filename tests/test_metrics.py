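"""Information, efficiency, silent-synapse counting, the Gaussian
false-positive approximation and the compressed-exponential fit."""

import numpy as np
import pytest

from sparseperceptron import (NoiseSpec, PatternSet, count_functional,
                              efficiency, error_rates,
                              fit_compressed_exponential, fp_rate_analytic,
                              gen_lures, gen_patterns, information,
                              information_closed_form,
                              normalize_to_unit_threshold,
                              optimize_threshold, prune_smallest, report,
                              solve_min_l1, solve_min_l2)

from _oracles import mutual_information_oracle, sample_compressed_exponential


class TestErrorRates:
    def test_zero_weights_never_fire(self):
        p = gen_patterns(50, 10, seed=0)
        lures = gen_lures(p, 10, seed=1)
        p10, p01 = error_rates(np.zeros(50), p, lures)
        assert (p10, p01) == (1.0, 0.0)

    def test_trained_state_has_no_false_negatives(self):
        from sparseperceptron import PlasticityConfig, train_online
        p = gen_patterns(100, 20, seed=2)
        res = train_online(p, PlasticityConfig(epsilon=0.01, lam=0.0,
                                               max_epochs=2000, seed=3))
        assert res.converged
        lures = gen_lures(p, 20, seed=4)
        p10, _ = error_rates(res.state.w, p, lures)
        assert p10 == 0.0

    def test_strong_noise_at_zero_threshold_is_a_coin_flip(self):
        rng_w = np.random.default_rng(5)
        w = rng_w.random(100)
        p = gen_patterns(100, 2000, seed=6)
        lures = gen_lures(p, 2000, seed=7)
        p10, p01 = error_rates(w, p, lures, theta=0.0, sigma=1e6, seed=8)
        assert abs(p10 - 0.5) < 0.05
        assert abs(p01 - 0.5) < 0.05

    def test_empty_test_sets_rejected(self):
        p = gen_patterns(10, 2, seed=0)
        with pytest.raises(ValueError):
            error_rates(np.zeros(10), p, gen_lures(p, 1, seed=1), sigma=-1.0)


class TestInformation:
    def test_perfect_discrimination_gives_two_k_over_n(self):
        assert information(0.0, 0.0, 100, 1000) == pytest.approx(0.2)

    def test_uninformative_output_gives_zero(self):
        assert information(1.0, 0.0, 100, 1000) == pytest.approx(0.0)

    def test_half_false_positive_rate_value(self):
        # (2K/N)·I at p01 = 1/2, p10 = 0 with 2K/N = 1
        assert information(0.5, 0.0, 500, 1000) == pytest.approx(
            0.311278, abs=1e-6)

    @pytest.mark.parametrize("p01", np.linspace(0.0, 1.0, 11))
    def test_closed_form_equals_general_formula_at_zero_p10(self, p01):
        oracle = 2 * 500 / 1000 * mutual_information_oracle(p01, 0.0)
        assert information_closed_form(p01, 500, 1000) == pytest.approx(
            oracle, abs=1e-12)

    @pytest.mark.parametrize("p01,p10", [(0.2, 0.1), (0.05, 0.3),
                                         (0.5, 0.5), (0.9, 0.01)])
    def test_general_formula_matches_joint_enumeration(self, p01, p10):
        oracle = 2 * 50 / 500 * mutual_information_oracle(p01, p10)
        assert information(p01, p10, 50, 500) == pytest.approx(oracle,
                                                               abs=1e-12)

    def test_information_decreases_with_false_positives(self):
        grid = np.linspace(0.0, 1.0, 21)
        vals = [information(p, 0.0, 100, 1000) for p in grid]
        assert np.all(np.diff(vals) < 0)


class TestEfficiency:
    def test_ratio(self):
        assert efficiency(0.3, 0.5) == pytest.approx(0.6)
        assert efficiency(0.2, 1.0) == pytest.approx(0.2)

    def test_dense_connectivity_is_the_lower_bound(self):
        assert efficiency(0.3, 0.7) >= 0.3

    def test_no_functional_synapses(self):
        assert efficiency(0.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            efficiency(0.1, 0.0)


class TestAnalyticFalsePositiveRate:
    def test_unit_stability_value(self):
        # θ√N/‖w‖₂ = 1 puts the threshold one s.d. into the lure tail
        w = np.array([np.sqrt(8.0), 0.0])  # ‖w‖ = √8, θ√N = √8 at N=8...
        p01 = fp_rate_analytic(np.full(4, 1.0), theta=1.0, N=4)
        assert p01 == pytest.approx(0.158655, abs=1e-6)

    def test_zero_threshold_gives_half(self):
        w = np.random.default_rng(0).random(50)
        assert fp_rate_analytic(w, theta=0.0, N=50) == pytest.approx(0.5)

    def test_silent_neuron_degenerate_limits(self):
        assert fp_rate_analytic(np.zeros(10), theta=1.0, N=10) == 0.0
        assert fp_rate_analytic(np.zeros(10), theta=0.0, N=10) == 1.0

    def test_matches_monte_carlo_for_qp_solution(self):
        p = gen_patterns(500, 150, seed=9)
        w = solve_min_l2(p).w
        lures = gen_lures(p, 40_000, seed=10)
        _, p01_emp = error_rates(w, p, lures)
        p01_ana = fp_rate_analytic(w, theta=1.0, N=500)
        se = np.sqrt(p01_emp * (1 - p01_emp) / 40_000)
        assert abs(p01_ana - p01_emp) < 3 * se + 2e-3


class TestCountFunctional:
    def test_exact_zeros_counted_by_both_modes(self):
        p = gen_patterns(50, 5, seed=11)
        w = solve_min_l1(p).w
        lures = gen_lures(p, 5000, seed=12)
        n_exact = int(np.sum(w == 0))
        for mode in ("info_drop", "threshold"):
            F, n_zero = count_functional(w, p, lures, mode=mode)
            assert n_zero == n_exact
            assert F == pytest.approx(1 - n_exact / 50)

    def test_threshold_count_insensitive_across_three_decades(self):
        # LP supports are well separated from solver dust
        p = gen_patterns(80, 16, seed=13)
        w = solve_min_l1(p).w
        lures = gen_lures(p, 100, seed=14)
        counts = {count_functional(w, p, lures, mode="threshold",
                                   w_zero_rel=tol)[1]
                  for tol in (1e-6, 1e-8, 1e-10)}
        assert len(counts) == 1

    def test_pruning_increments_the_zero_count(self):
        p = gen_patterns(60, 20, seed=15)  # LP support size ≲ K = 20
        w = solve_min_l1(p).w
        lures = gen_lures(p, 6000, seed=16)
        # threshold mode counts the support exactly, so deletion shifts it
        # one for one
        _, n0 = count_functional(w, p, lures, mode="threshold")
        _, n1 = count_functional(prune_smallest(w, 3), p, lures,
                                 mode="threshold")
        assert n1 == n0 + 3

    def test_all_silent_vector(self):
        p = gen_patterns(20, 2, seed=17)
        lures = gen_lures(p, 10, seed=18)
        F, n_zero = count_functional(np.zeros(20), p, lures)
        assert (F, n_zero) == (0.0, 20)


class TestNormalization:
    def test_unit_minimal_response(self):
        p = PatternSet(np.ones((1, 2)))
        out = normalize_to_unit_threshold(np.array([2.0, 2.0]), p)
        assert np.allclose(out, [0.5, 0.5])

    def test_solver_solutions_reach_exactly_one(self):
        p = gen_patterns(60, 12, seed=19)
        for sol in (solve_min_l1(p), solve_min_l2(p)):
            w = normalize_to_unit_threshold(sol.w, p)
            assert (p.data @ w).min() == pytest.approx(1.0)

    def test_scaling_preserves_support(self):
        p = gen_patterns(60, 12, seed=20)
        w = solve_min_l1(p).w
        out = normalize_to_unit_threshold(w, p)
        assert np.array_equal(out > 0, w > 0)

    def test_nonpositive_response_is_a_state_error(self):
        p = PatternSet(np.array([[1.0, -1.0]]))
        with pytest.raises(RuntimeError):
            normalize_to_unit_threshold(np.array([0.0, 1.0]), p)


class TestCompressedExponentialFit:
    def test_recovers_exponential_law(self, rng):
        samples = sample_compressed_exponential(1.0, 2.0, 100_000, rng)
        fit = fit_compressed_exponential(samples)
        assert fit.beta == pytest.approx(1.0, abs=0.02)
        assert fit.c == pytest.approx(2.0, abs=0.04)

    def test_recovers_compressed_law(self, rng):
        samples = sample_compressed_exponential(1.4, 2.0, 100_000, rng)
        fit = fit_compressed_exponential(samples)
        assert fit.beta == pytest.approx(1.4, abs=0.03)

    def test_recovers_hemi_gaussian(self, rng):
        samples = sample_compressed_exponential(2.0, 1.0, 100_000, rng)
        fit = fit_compressed_exponential(samples)
        assert fit.beta == pytest.approx(2.0, abs=0.05)

    def test_nonpositive_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_compressed_exponential(np.array([0.5, -0.1, 0.2]))


class TestOptimizeThreshold:
    def test_single_grid_point_is_returned(self):
        p = gen_patterns(50, 5, seed=21)
        lures = gen_lures(p, 50, seed=22)
        theta, _ = optimize_threshold(np.ones(50), p, lures, NoiseSpec(),
                                      np.array([0.7]), seed=23)
        assert theta == 0.7

    def test_noise_free_optimum_beats_training_threshold(self):
        p = gen_patterns(100, 10, seed=24)
        w = solve_min_l2(p).w
        lures = gen_lures(p, 1000, seed=25)
        w_n = w / (p.data @ w).mean()
        base_theta = (p.data @ w_n).min() / np.sqrt(100)
        _, C_star = optimize_threshold(w, p, lures, NoiseSpec(),
                                       np.linspace(0.1, 1.5, 15) * base_theta,
                                       seed=26)
        p10, p01 = error_rates(w, p, lures)
        assert C_star >= information(p01, p10, 10, 100) - 1e-12

    def test_pure_noise_patterns_carry_no_information(self):
        # δ = 1/2 at f = 1/2 makes distorted patterns indistinguishable
        # from lures
        p = gen_patterns(200, 20, coding="binary01", f=0.5, seed=27)
        w = np.random.default_rng(28).random(200)
        noise = NoiseSpec(delta01=0.5, delta10=0.5)
        lures = gen_lures(p, 2000, noise=noise, seed=29)
        _, C_star = optimize_threshold(w, p, lures, noise,
                                       np.linspace(0.0, 2.0, 21), seed=30)
        assert C_star < 0.15 * (2 * 20 / 200)


def test_report_bundles_consistent_numbers():
    p = gen_patterns(80, 8, seed=31)
    lures = gen_lures(p, 800, seed=32)
    w = solve_min_l1(p).w
    rep = report(w, p, lures)
    assert rep.p10 == 0.0
    assert rep.C == pytest.approx(information(rep.p01, rep.p10, 8, 80))
    assert rep.S == pytest.approx(rep.C / rep.F)
    assert rep.l1 == pytest.approx(w.sum())
    assert rep.l2 == pytest.approx(np.linalg.norm(w))
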