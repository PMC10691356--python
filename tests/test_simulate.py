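"""Synthetic-data generator: determinism, noise models, calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import oceanmix as om
from oceanmix.cohort import TOTAL, simulate_cohort
from oceanmix.simulate import Scenario, default_scenario, simulate_dataset


class TestScenarios:
    def test_toy_dimensions(self, toy_scenario):
        idx = toy_scenario.config.index
        assert idx.n_stocks == 2 and idx.n_regions == 4 and idx.n_years == 6
        # one distribution simplex per stock and season
        assert toy_scenario.truth.pi.shape == (2, 4, 4)
        sums = toy_scenario.truth.pi.sum(axis=-1)
        assert np.allclose(sums, 1.0)

    def test_reduced_dimensions(self):
        sc = default_scenario("reduced", seed=3)
        idx = sc.config.index
        assert idx.n_stocks == 4 and idx.n_regions == 8 and idx.n_years == 10

    def test_coastwide_release_sizes_within_realistic_range(self):
        sc = default_scenario("coastwide", seed=5)
        sizes = [g.release_size for g in sc.release_plan]
        assert min(sizes) >= 9_000
        assert max(sizes) <= 3_500_000

    def test_coastwide_has_no_winter_gsi_and_sparse_north(self):
        sc = default_scenario("coastwide", seed=5)
        seasons = {k[1] for k, _ in sc.gsi_plan}
        assert "winter" not in seasons
        idx = sc.config.index
        south = sum(1 for k, _ in sc.gsi_plan if idx.region_i(k[0]) < 5)
        north = sum(1 for k, _ in sc.gsi_plan if idx.region_i(k[0]) >= 5)
        assert north < south

    def test_distribution_truth_shifts_north_with_natal_region(self):
        sc = default_scenario("reduced", seed=3)
        pi = sc.truth.pi
        centers = (pi * np.arange(pi.shape[-1])).sum(axis=-1)
        # stocks are ordered south -> north by natal region
        assert np.all(np.diff(centers.mean(axis=1)) > 0)

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValueError, match="unknown scale"):
            default_scenario("huge")

    def test_misassignment_must_be_row_stochastic(self, toy_scenario):
        bad = np.eye(3) * 0.5
        with pytest.raises(ValueError, match="row-stochastic"):
            dataclasses.replace(toy_scenario, misassignment=bad)


class TestSimulateDataset:
    def test_same_seed_gives_byte_identical_fixtures(self, tmp_path):
        for run in ("a", "b"):
            sc = default_scenario("toy", seed=42)
            bundle, truth = simulate_dataset(sc)
            om.write_fixture(bundle, truth, tmp_path / run, config=sc.config)
        for name in ("releases.csv", "cwt_recoveries.csv", "gsi_samples.csv",
                     "run_sizes.csv", "landings.csv", "age_counts.csv",
                     "truth.yaml"):
            a = (tmp_path / "a" / name).read_bytes()
            b = (tmp_path / "b" / name).read_bytes()
            assert a == b, name

    def test_different_seeds_differ(self):
        b1, _ = simulate_dataset(default_scenario("toy", seed=1))
        b2, _ = simulate_dataset(default_scenario("toy", seed=2))
        assert not b1.cwt_recoveries.observed.equals(b2.cwt_recoveries.observed)

    def test_zero_sampling_fraction_yields_no_recovery_rows(self, toy_scenario):
        sc = dataclasses.replace(
            toy_scenario,
            truth=dataclasses.replace(
                toy_scenario.truth, lam=np.zeros_like(toy_scenario.truth.lam)
            ),
        )
        bundle, _ = simulate_dataset(sc)
        assert len(bundle.cwt_recoveries) == 0

    def test_recovery_rows_enumerate_sampled_strata_including_zeros(
            self, toy_data, toy_scenario):
        bundle, truth = toy_data
        # one row per (group, visited stratum with lambda > 0)
        idx = toy_scenario.config.index
        groups = {g.id: g for g in toy_scenario.release_plan}
        n_expected = 0
        for g in groups.values():
            steps = om.season_step_iterator(idx, g.brood_year)
            n_expected += len(steps) * idx.n_regions * idx.n_gears
        assert len(bundle.cwt_recoveries) == n_expected
        assert (bundle.cwt_recoveries.observed == 0).any()

    def test_degenerate_noise_recovers_expectations_exactly(self, toy_scenario):
        truth = dataclasses.replace(
            toy_scenario.truth, sigma_run=1e-12, cv_land=1e-12
        )
        sc = dataclasses.replace(toy_scenario, truth=truth)
        bundle, _ = simulate_dataset(sc)
        groups = sc.all_groups()
        by_id = {g.id: g for g in groups}
        idx = sc.config.index
        states = [
            simulate_cohort(g, truth, idx, by_id)
            for g in groups if g.group_class == TOTAL
        ]
        for row in bundle.run_sizes.itertuples(index=False):
            expected = om.expected_run_size(states, row.stock, int(row.year))
            assert row.estimate == pytest.approx(expected, rel=1e-9)
        for row in bundle.landings.head(20).itertuples(index=False):
            stratum = (row.region, row.season, int(row.year), row.gear)
            mu = om.expected_stock_catch(states, stratum, idx)
            p2 = truth.p2_for(idx, stratum)
            assert row.estimate == pytest.approx(mu.sum() / p2, rel=1e-6)

    def test_large_sample_gsi_converges_to_true_composition(self, toy_scenario):
        # law of large numbers at n = 200k: observed shares within 3 SE
        big = [(k, 200_000) for k, _ in toy_scenario.gsi_plan[:4]]
        sc = dataclasses.replace(toy_scenario, gsi_plan=big)
        bundle, truth = simulate_dataset(sc)
        groups = sc.all_groups()
        by_id = {g.id: g for g in groups}
        idx = sc.config.index
        states = [
            simulate_cohort(g, truth, idx, by_id)
            for g in groups if g.group_class == TOTAL
        ]
        for row in bundle.gsi_samples.itertuples(index=False):
            stratum = (row.region, row.season, int(row.year), row.gear)
            mu = om.expected_stock_catch(states, stratum, idx)
            p2 = truth.p2_for(idx, stratum)
            comp = om.expected_composition(
                mu, om.expand_to_total_catch(float(mu.sum()), p2)
            )
            obs = np.array([getattr(row, s) for s in idx.stocks] + [row.other])
            obs = obs / row.n
            se = np.sqrt(comp * (1 - comp) / row.n)
            assert np.all(np.abs(obs - comp) <= 3 * se + 1e-12)

    def test_misassignment_moves_mass_between_stocks(self, toy_scenario):
        k = toy_scenario.config.index.n_stocks + 1
        mis = np.full((k, k), 0.15 / (k - 1))
        np.fill_diagonal(mis, 0.85)
        sc = dataclasses.replace(toy_scenario, misassignment=mis)
        bundle_mis, _ = simulate_dataset(sc)
        bundle_id, _ = simulate_dataset(toy_scenario)
        # soft sums remain a partition of n in both cases
        idx = toy_scenario.config.index
        sums = bundle_mis.gsi_samples[list(idx.stocks)].sum(axis=1)
        total = sums + bundle_mis.gsi_samples.other
        assert np.allclose(total, bundle_mis.gsi_samples.n)
        # identity case yields integer (hard) counts, confusion case does not
        assert np.allclose(bundle_id.gsi_samples[idx.stocks[0]] % 1, 0)
        frac = bundle_mis.gsi_samples[idx.stocks[0]] % 1
        assert (frac > 1e-9).any()

    def test_loglik_finite_at_truth(self, toy_scenario, toy_data):
        bundle, truth = toy_data
        val = om.total_loglik(
            truth, bundle, toy_scenario.config,
            components=om.likelihoods.VARIANTS["cwt_gsi_age"] | {"p2_hier"},
        )
        assert np.isfinite(val)

    def test_observation_zscores_are_calibrated(self, toy_scenario, toy_data):
        # standardized residuals of run sizes under the generating truth
        bundle, truth = toy_data
        groups = toy_scenario.all_groups()
        by_id = {g.id: g for g in groups}
        idx = toy_scenario.config.index
        states = [
            simulate_cohort(g, truth, idx, by_id)
            for g in groups if g.group_class == TOTAL
        ]
        z = []
        for row in bundle.run_sizes.itertuples(index=False):
            expected = om.expected_run_size(states, row.stock, int(row.year))
            z.append(np.log(row.estimate / expected) / truth.sigma_run)
        z = np.array(z)
        assert abs(z.mean()) < 3.0 / np.sqrt(len(z))
        assert 0.4 < z.std() < 1.8


class TestWriteFixture:
    def test_round_trip_is_lossless_and_stable(self, toy_data, toy_scenario,
                                               tmp_path):
        bundle, truth = toy_data
        om.write_fixture(bundle, truth, tmp_path / "first",
                         config=toy_scenario.config)
        back = om.read_observations(tmp_path / "first", toy_scenario.config)
        assert bundle.equals(back)
        om.write_fixture(back, truth, tmp_path / "second",
                         config=toy_scenario.config)
        for name in ("releases.csv", "cwt_recoveries.csv", "gsi_samples.csv"):
            assert ((tmp_path / "first" / name).read_bytes()
                    == (tmp_path / "second" / name).read_bytes())

    def test_truth_file_round_trips_every_field(self, toy_data, tmp_path,
                                                toy_scenario):
        bundle, truth = toy_data
        om.write_fixture(bundle, truth, tmp_path)
        back = om.read_truth(tmp_path)
        assert np.allclose(back.pi, truth.pi)
        assert np.allclose(back.f, truth.f)
        assert back.M0 == pytest.approx(truth.M0)
        assert back.U == pytest.approx(truth.U)
        assert back.p2 == pytest.approx(truth.p2)
        assert back.phi == truth.phi
        assert back.sigma_p2 == truth.sigma_p2
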