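"""Observation-model components against independent density oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

import oceanmix as om
from oceanmix.likelihoods import (
    VARIANTS,
    age_loglik,
    cwt_loglik,
    gsi_loglik,
    landings_loglik,
    modeled_age_proportions,
    p2_hierarchical_loglik,
    p2_loglik,
    runsize_loglik,
    total_loglik,
    zoid_loglik,
    zoid_pattern_logprob,
    zoid_zero_prob,
)


class TestNegativeBinomial:
    def test_matches_scipy_pmf_on_randomized_cases(self, rng):
        for _ in range(120):
            mu = rng.uniform(0.01, 50.0)
            tau = rng.uniform(0.2, 40.0)
            y = int(rng.integers(0, 80))
            oracle = stats.nbinom.logpmf(y, tau, tau / (tau + mu))
            assert cwt_loglik(y, mu, tau) == pytest.approx(oracle, abs=1e-8)

    def test_degenerate_zero_mean_zero_count(self):
        assert cwt_loglik(0, 1e-12, 5.0) == pytest.approx(0.0, abs=1e-6)

    def test_poisson_limit(self):
        poisson = stats.poisson.logpmf(3, 2.5)
        assert cwt_loglik(3, 2.5, 1e7) == pytest.approx(poisson, abs=1e-4)

    def test_zero_prediction_with_positive_count_stays_finite(self):
        assert np.isfinite(cwt_loglik(2, 0.0, 5.0))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cwt_loglik(-1, 1.0, 5.0)
        with pytest.raises(ValueError):
            cwt_loglik(1, 1.0, 0.0)

    def test_unimodal_with_analytic_mode(self):
        mu, tau = 12.0, 6.0
        lls = [cwt_loglik(y, mu, tau) for y in range(0, 60)]
        peak = int(np.argmax(lls))
        mode = np.floor((tau - 1.0) * mu / tau)  # NB mode (ties one below)
        assert peak in (mode - 1, mode)
        assert all(np.diff(lls[peak:]) < 0) and all(np.diff(lls[: peak - 1]) > 0)


class TestZoid:
    def test_two_categories_reduce_to_beta_density(self, rng):
        for _ in range(100):
            p = rng.uniform(0.05, 0.95)
            phi = rng.uniform(0.5, 60.0)
            n = rng.integers(5, 300)
            y1 = rng.uniform(0.01, 0.99)
            y = np.array([y1, 1.0 - y1])
            pv = np.array([p, 1.0 - p])
            theta0 = (1.0 - pv) ** n
            pattern = np.log((1 - theta0[0]) * (1 - theta0[1])) - np.log(
                1.0 - theta0.prod()
            )
            beta = stats.beta.logpdf(y1, phi * p, phi * (1.0 - p))
            assert zoid_loglik(y, pv, phi, n) == pytest.approx(
                pattern + beta, abs=1e-8
            )

    def test_structural_zero_factor_matches_definition(self):
        # one fish, p = 0.5: absence probability (1 - 0.5)^1 = 0.5
        theta0 = zoid_zero_prob(np.array([0.5, 0.5]), 1)
        assert theta0[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("K", [2, 3, 4])
    def test_pattern_probabilities_sum_to_one(self, K, rng):
        p = rng.dirichlet(np.ones(K))
        n = float(rng.integers(2, 50))
        total = 0.0
        for pattern in itertools.product([False, True], repeat=K):
            zero = np.array(pattern)
            if zero.all():
                continue  # inadmissible: no positive component
            total += np.exp(zoid_pattern_logprob(zero, p, n))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_conditional_density_integrates_to_one(self, rng):
        # Monte-Carlo integral of the 3-category conditional density over
        # the positive sub-simplex (uniform sampling, within 3 SE)
        p = np.array([0.3, 0.5, 0.2])
        phi, n = 8.0, 40
        pattern = np.log((1 - (1 - p) ** n).prod()) - np.log(
            1 - ((1 - p) ** n).prod()
        )
        m = 40_000
        y1 = rng.uniform(0, 1, size=m)
        y2 = rng.uniform(0, 1, size=m)
        keep = y1 + y2 < 1.0
        ys = np.column_stack([y1[keep], y2[keep], 1 - y1[keep] - y2[keep]])
        vals = np.array([
            np.exp(zoid_loglik(y, p, phi, n) - pattern) for y in ys
        ])
        # area of the simplex {y1 + y2 < 1} in (y1, y2) coordinates is 1/2
        integral = 0.5 * vals.mean()
        se = 0.5 * vals.std() / np.sqrt(keep.sum())
        assert abs(integral - 1.0) < 3 * se + 0.01

    def test_one_inflation_is_pure_pattern_probability(self):
        p = np.array([0.6, 0.4])
        n = 10
        y = np.array([1.0, 0.0])
        theta0 = (1 - p) ** n
        expected = np.log((1 - theta0[0]) * theta0[1]) - np.log(1 - theta0.prod())
        assert zoid_loglik(y, p, 5.0, n) == pytest.approx(expected, abs=1e-10)

    def test_smaller_phi_flattens_the_conditional_density(self):
        y_mode = np.array([0.3, 0.7])
        y_off = np.array([0.7, 0.3])
        p = np.array([0.3, 0.7])
        sharp = zoid_loglik(y_mode, p, 50.0, 100) - zoid_loglik(y_off, p, 50.0, 100)
        flat = zoid_loglik(y_mode, p, 2.0, 100) - zoid_loglik(y_off, p, 2.0, 100)
        assert sharp > flat > 0

    def test_invalid_compositions_rejected(self):
        with pytest.raises(ValueError):
            zoid_loglik(np.array([0.5, 0.4]), np.array([0.5, 0.5]), 5.0, 10)
        with pytest.raises(ValueError):
            zoid_loglik(np.array([-0.1, 1.1]), np.array([0.5, 0.5]), 5.0, 10)


class TestGsiRow:
    def test_hard_assignment_row_normalizes_to_published_example(self):
        # 12 of 200 sampled fish assigned to the first focal stock
        sums = np.array([12.0, 0.0, 0.0, 0.0])
        comp = np.array([0.06, 0.01, 0.01, 0.01, 0.91])
        ll = gsi_loglik(sums, 188.0, 200.0, comp, phi=20.0)
        y = np.array([0.06, 0, 0, 0, 0.94])
        manual = zoid_loglik(y, comp, 20.0, 200.0)
        assert ll == pytest.approx(manual, abs=1e-10)

    def test_soft_assignments_equal_hard_assignments_of_same_mass(self):
        comp = np.array([0.3, 0.3, 0.4])
        soft = gsi_loglik(np.array([1.0, 1.0]), 0.0, 2.0, comp, 5.0)
        hard = gsi_loglik(np.array([1.0, 1.0]), 0.0, 2.0, comp, 5.0)
        assert soft == hard  # two fish at 0.5/0.5 sum to one per stock

    def test_partition_violation_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            gsi_loglik(np.array([5.0, 5.0]), 100.0, 200.0,
                       np.array([0.3, 0.3, 0.4]), 5.0)

    def test_observation_at_expectation_maximizes_conditional_density(self):
        comp = np.array([0.5, 0.3, 0.2])
        n, phi = 50.0, 30.0  # phi * p_k > 1 for all k
        best = gsi_loglik(comp[:2] * n, comp[2] * n, n, comp, phi)
        for eps in (-0.1, -0.05, 0.05, 0.1):
            y = comp + np.array([eps, -eps, 0.0])
            ll = gsi_loglik(y[:2] * n, y[2] * n, n, comp, phi)
            assert ll < best


class TestFocalProportion:
    def test_binomial_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 400))
            k = int(rng.integers(0, n + 1))
            p = rng.uniform(0.01, 0.99)
            oracle = stats.binom.logpmf(k, n, p)
            assert p2_loglik(k, n, p) == pytest.approx(oracle, abs=1e-8)

    def test_certain_success(self):
        assert p2_loglik(10, 10, 1.0 - 1e-12) == pytest.approx(0.0, abs=1e-9)

    def test_all_failures_closed_form(self):
        assert p2_loglik(0, 10, 0.3) == pytest.approx(10 * np.log(0.7), abs=1e-10)

    def test_soft_sum_rounds_to_nearest_count(self):
        assert p2_loglik(49.6, 100, 0.5) == p2_loglik(50, 100, 0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            p2_loglik(11, 10, 0.5)


class TestHierarchy:
    def test_normal_oracle_at_one_sd(self):
        p2bar, sigma = 0.4, 0.6
        p2 = 1.0 / (1.0 + np.exp(-(p2bar + sigma)))
        ll = p2_hierarchical_loglik([p2], p2bar, sigma)
        assert ll == pytest.approx(stats.norm.logpdf(p2bar + sigma, p2bar, sigma),
                                   abs=1e-8)

    def test_density_maximal_at_the_regional_mean(self):
        p2bar = 0.8
        at_mean = p2_hierarchical_loglik([1 / (1 + np.exp(-p2bar))], p2bar, 0.5)
        off = p2_hierarchical_loglik([1 / (1 + np.exp(-p2bar - 0.3))], p2bar, 0.5)
        assert at_mean > off

    def test_degenerate_sigma_with_mismatch_diverges(self):
        vals = []
        for sigma in (1e-2, 1e-4, 1e-6):
            vals.append(p2_hierarchical_loglik([0.3], 1.5, sigma))
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < -1e6

    def test_boundary_values_rejected(self):
        with pytest.raises(ValueError):
            p2_hierarchical_loglik([1.0], 0.0, 0.5)


class TestRunSizeAndLandings:
    def test_lognormal_oracle(self, rng):
        for _ in range(100):
            expected = rng.uniform(1e2, 1e6)
            sigma = rng.uniform(0.05, 1.0)
            observed = expected * np.exp(sigma * rng.standard_normal())
            oracle = stats.norm.logpdf(np.log(observed), np.log(expected), sigma)
            assert runsize_loglik(observed, expected, sigma) == pytest.approx(
                oracle, abs=1e-8
            )

    def test_log_ratio_invariance_under_common_scaling(self):
        a = runsize_loglik(1200.0, 1000.0, 0.3)
        b = runsize_loglik(2400.0, 2000.0, 0.3)
        assert a == pytest.approx(b, abs=1e-12)

    def test_landings_normal_cv_oracle(self, rng):
        for _ in range(100):
            mu = rng.uniform(1e2, 1e6)
            cv = rng.uniform(0.05, 0.5)
            obs = mu * (1.0 + cv * rng.standard_normal())
            oracle = stats.norm.logpdf(obs, mu, cv * mu)
            assert landings_loglik(obs, mu, cv) == pytest.approx(oracle, abs=1e-8)

    def test_landings_peak_density_value(self):
        mu, cv = 5000.0, 0.2
        assert landings_loglik(mu, mu, cv) == pytest.approx(
            -np.log(np.sqrt(2 * np.pi) * cv * mu), abs=1e-10
        )

    def test_landings_scaling_shifts_log_density_by_log_scale(self):
        base = landings_loglik(1100.0, 1000.0, 0.2)
        scaled = landings_loglik(11_000.0, 10_000.0, 0.2)
        assert scaled == pytest.approx(base - np.log(10.0), abs=1e-10)

    def test_one_sd_deviation(self):
        mu, cv = 1000.0, 0.15
        peak = landings_loglik(mu, mu, cv)
        one_sd = landings_loglik(mu + cv * mu, mu, cv)
        assert peak - one_sd == pytest.approx(0.5, abs=1e-10)


class TestAgeComposition:
    def test_multinomial_oracle(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 5))
            p3 = rng.dirichlet(np.ones(k))
            A = rng.multinomial(int(rng.integers(5, 200)), p3)
            oracle = stats.multinomial.logpmf(A, A.sum(), p3)
            assert age_loglik(A, p3) == pytest.approx(oracle, abs=1e-8)

    def test_certain_age_class(self):
        assert age_loglik(np.array([17, 0, 0]), np.array([1.0, 0, 0])) == 0.0

    def test_small_count_example(self):
        oracle = stats.multinomial.logpmf([2, 1, 1], 4, [0.5, 0.25, 0.25])
        assert age_loglik(np.array([2, 1, 1]),
                          np.array([0.5, 0.25, 0.25])) == pytest.approx(oracle)

    def test_permutation_invariance(self, rng):
        A = np.array([5.0, 2.0, 9.0])
        p3 = np.array([0.2, 0.5, 0.3])
        perm = rng.permutation(3)
        assert age_loglik(A, p3) == pytest.approx(age_loglik(A[perm], p3[perm]))

    def test_unsupported_age_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            age_loglik(np.array([1.0, 2.0]), np.array([1.0, 0.0]))


class TestTotalLoglik:
    def test_all_components_off_returns_prior_only(self, toy_scenario, toy_data):
        bundle, truth = toy_data
        val = total_loglik(truth, bundle, toy_scenario.config, components=set(),
                           log_prior=lambda p: -7.5)
        assert val == -7.5

    def test_cwt_only_variant_is_pure_recovery_sum(self, toy_scenario, toy_data):
        bundle, truth = toy_data
        via_variant = total_loglik(truth, bundle, toy_scenario.config,
                                   components="cwt_only")
        via_set = total_loglik(truth, bundle, toy_scenario.config,
                               components={"cwt"})
        assert via_variant == pytest.approx(via_set, abs=1e-12)

    def test_component_sum_matches_brute_force_accumulation(
            self, toy_scenario, toy_data):
        bundle, truth = toy_data
        comps = VARIANTS["cwt_gsi_age"] | {"p2_hier"}
        total = total_loglik(truth, bundle, toy_scenario.config, components=comps)
        parts = sum(
            total_loglik(truth, bundle, toy_scenario.config, components={c})
            for c in comps
        )
        assert total == pytest.approx(parts, abs=1e-8)

    def test_variant_additivity(self, toy_scenario, toy_data):
        bundle, truth = toy_data
        cwt = total_loglik(truth, bundle, toy_scenario.config, components={"cwt"})
        gsi_block = total_loglik(
            truth, bundle, toy_scenario.config,
            components=VARIANTS["cwt_gsi"] - {"cwt"},
        )
        both = total_loglik(truth, bundle, toy_scenario.config,
                            components="cwt_gsi")
        assert both == pytest.approx(cwt + gsi_block, abs=1e-8)

    def test_finite_at_truth(self, toy_scenario, toy_data):
        bundle, truth = toy_data
        comps = VARIANTS["cwt_gsi_age"] | {"p2_hier"}
        assert np.isfinite(
            total_loglik(truth, bundle, toy_scenario.config, components=comps)
        )
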