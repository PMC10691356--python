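"""Deterministic cohort dynamics: entry, mortality, maturation, catches."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oceanmix.cohort import (
    CohortState,
    ModelStructureError,
    ParameterSet,
    ReleaseGroup,
    entry_abundance,
    expand_to_total_catch,
    expected_composition,
    expected_cwt_recoveries,
    expected_run_size,
    expected_stock_catch,
    make_total_groups,
    simulate_cohort,
    step_abundance,
)
from oceanmix.index import ModelIndex, Step


def make_index(**kw):
    base = dict(
        stocks=("SFB", "KLT"),
        regions=("MONT", "SFB", "MEN", "NCA"),
        years=(2000, 2007),
        ages=(2, 3),
        gears=("troll",),
    )
    base.update(kw)
    return ModelIndex(**base)


def make_params(index, f_value=0.0, M_value=0.1, m_young=0.2, pi=None,
                lam_value=0.0, **kw):
    L, S, C, G = index.n_regions, index.n_seasons, index.n_years, index.n_gears
    if pi is None:
        pi = np.full((index.n_stocks, S, L), 1.0 / L)
    m = np.full((index.n_stocks, index.n_ages), m_young)
    m[:, -1] = 1.0
    defaults = dict(
        pi=pi,
        f=np.full((L, S, C, G), f_value),
        m=m,
        M=np.full(index.n_ages, M_value),
        lam=np.full((L, S, C, G), lam_value),
    )
    defaults.update(kw)
    return ParameterSet(**defaults)


def cwt_group(stock="SFB", brood=2000, R=1000.0, gid="g1"):
    return ReleaseGroup(gid, stock, brood, "cwt", release_size=R)


class TestEntryAbundance:
    def test_zero_mortality_identity(self):
        params = make_params(make_index())
        assert entry_abundance(cwt_group(R=1000.0), params) == 1000.0

    def test_log_two_mortality_halves_the_release(self):
        # closed form: 1000 * exp(-ln 2) = 500
        params = make_params(make_index(), M0={"g1": np.log(2.0)})
        assert entry_abundance(cwt_group(R=1000.0), params) == pytest.approx(500.0)

    def test_deviation_shared_with_m0_in_exponent(self):
        params = make_params(
            make_index(), M0={"g1": 0.3}, delta={("SFB", 2000): 0.7}
        )
        assert entry_abundance(cwt_group(R=1000.0), params) == pytest.approx(
            1000.0 * np.exp(-1.0)
        )

    def test_total_entry_is_cwt_entry_plus_untagged(self):
        cwt = cwt_group(R=1000.0)
        total = make_total_groups([cwt])[0]
        params = make_params(
            make_index(), M0={"g1": np.log(2.0)}, U={total.id: 2000.0}
        )
        by_id = {cwt.id: cwt}
        entry = entry_abundance(total, params, by_id)
        assert entry == pytest.approx(2500.0)
        assert entry >= entry_abundance(cwt, params)

    def test_total_without_link_raises(self):
        orphan = ReleaseGroup("t", "SFB", 2000, "total")
        with pytest.raises(ModelStructureError, match="linked"):
            entry_abundance(orphan, make_params(make_index()), {})


class TestStepAbundance:
    def test_no_mortality_identity(self):
        index = make_index()
        params = make_params(index, f_value=0.0, M_value=1e-300)
        step = Step(2002, "summer", 2)
        n_next, catch, nat, mat = step_abundance(1000.0, step, 0, params, index)
        assert n_next == pytest.approx(1000.0, rel=1e-12)
        assert np.all(catch == 0.0) and mat == 0.0

    def test_baranov_closed_form_single_region(self):
        # independent evaluation of the Baranov identity
        index = make_index(regions=("MONT", "SFB"))
        pi = np.zeros((2, 4, 2))
        pi[:, :, 0] = 1.0  # everything in one region
        params = make_params(index, pi=pi, M_value=0.1)
        params.f[:] = 0.2
        step = Step(2002, "summer", 2)
        n_next, catch, nat, mat = step_abundance(1000.0, step, 0, params, index)
        Z = 0.3
        expected_catch = 1000.0 * (0.2 / Z) * (1.0 - np.exp(-Z))
        assert catch[0, 0] == pytest.approx(expected_catch, rel=1e-12)
        assert n_next == pytest.approx(1000.0 * np.exp(-Z), rel=1e-12)
        assert nat == pytest.approx(1000.0 * (0.1 / Z) * (1.0 - np.exp(-Z)), rel=1e-12)

    def test_fall_with_certain_maturation_empties_the_ocean(self):
        index = make_index()
        params = make_params(index, m_young=1.0, M_value=0.05)
        step = Step(2002, "fall", 2)
        n_next, catch, nat, mat = step_abundance(500.0, step, 0, params, index)
        assert n_next == 0.0
        assert mat == pytest.approx(500.0 * np.exp(-0.05), rel=1e-12)

    def test_negative_rates_rejected(self):
        index = make_index()
        params = make_params(index)
        params.f[0, 0, 0, 0] = -0.1
        with pytest.raises(ValueError, match="negative fishing"):
            step_abundance(10.0, Step(2000, "spring", 2), 0, params, index)

    @pytest.mark.parametrize("equation", ["baranov", "sequential"])
    def test_conservation_within_one_step(self, equation):
        index = make_index()
        rng = np.random.default_rng(5)
        pi_row = rng.dirichlet(np.ones(4))
        pi = np.tile(pi_row, (2, 4, 1))
        params = make_params(index, pi=pi, M_value=0.08)
        params.f[:] = rng.uniform(0, 0.4, size=params.f.shape)
        step = Step(2002, "fall", 2)
        N = 1234.5
        n_next, catch, nat, mat = step_abundance(
            N, step, 0, params, index, catch_equation=equation
        )
        assert N == pytest.approx(n_next + catch.sum() + nat + mat, rel=1e-9)


class TestSimulateCohort:
    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_fish_conserved_at_every_step_for_random_parameters(self, seed):
        rng = np.random.default_rng(seed)
        index = make_index()
        pi = rng.dirichlet(np.ones(4), size=(2, 4))
        params = make_params(
            index, pi=pi, M_value=float(rng.uniform(0.02, 0.3)),
            m_young=float(rng.uniform(0, 1)),
            M0={"g1": float(rng.uniform(0, 3))},
        )
        params.f[:] = rng.uniform(0, 0.5, size=params.f.shape)
        state = simulate_cohort(cwt_group(R=float(rng.uniform(1e3, 1e6))),
                                params, index)
        for t in range(len(state.steps)):
            balance = (state.N[t + 1] + state.catch[t].sum()
                       + state.natural_deaths[t] + state.matured[t])
            assert state.N[t] == pytest.approx(balance, rel=1e-9)
        assert np.all(np.diff(state.N) <= 1e-9)  # removals only

    def test_zero_fishing_matches_analytic_trajectory(self):
        index = make_index(ages=(2, 4), years=(2000, 2010))
        params = make_params(index, f_value=0.0, M_value=0.1, m_young=0.25,
                             M0={"g1": 0.5})
        state = simulate_cohort(cwt_group(R=10_000.0), params, index)
        # closed form: entry * exp(-sum M) * prod (1 - m) over past falls
        N = 10_000.0 * np.exp(-0.5)
        for t, step in enumerate(state.steps):
            assert state.N[t] == pytest.approx(N, rel=1e-12)
            N *= np.exp(-0.1)
            if step.season == "fall":
                N *= (1.0 - 0.25) if step.age < index.terminal_age else 0.0
        assert state.N[-1] == pytest.approx(0.0, abs=1e-9)

    def test_total_group_dominates_linked_cwt_group_at_every_step(self):
        index = make_index()
        cwt = cwt_group(R=50_000.0)
        total = make_total_groups([cwt])[0]
        params = make_params(index, M_value=0.1, m_young=0.3,
                             M0={"g1": 1.2}, U={total.id: 30_000.0})
        params.f[:] = 0.15
        by_id = {cwt.id: cwt, total.id: total}
        s_cwt = simulate_cohort(cwt, params, index, by_id)
        s_tot = simulate_cohort(total, params, index, by_id)
        assert np.all(s_tot.N >= s_cwt.N - 1e-9)


class TestDerivedExpectations:
    def test_recoveries_scale_linearly_with_sampling_fraction(self):
        index = make_index()
        params = make_params(index, lam_value=1.0)
        params.f[:] = 0.2
        state = simulate_cohort(cwt_group(), params, index)
        full = expected_cwt_recoveries(state, params, index)
        t0 = state.steps[0]
        key = ("MONT", t0.season, t0.year, "troll")
        assert full[key] == pytest.approx(state.catch[0, 0, 0])

        params.lam[:] = 0.25
        quarter = expected_cwt_recoveries(state, params, index)
        assert quarter[key] == pytest.approx(0.25 * full[key])

        params.lam[:] = 0.0
        assert all(v == 0.0 for v in expected_cwt_recoveries(
            state, params, index).values())

    def test_quarter_sampling_arithmetic(self):
        assert 0.25 * 80.0 == 20.0  # documented oracle for the lambda scaling
        index = make_index()
        params = make_params(index, lam_value=0.25)
        params.f[:] = 0.3
        state = simulate_cohort(cwt_group(), params, index)
        recs = expected_cwt_recoveries(state, params, index)
        t0 = state.steps[0]
        assert recs[("SFB", t0.season, t0.year, "troll")] == pytest.approx(
            0.25 * state.catch[0, 1, 0]
        )

    def test_stock_catch_sums_across_ages(self):
        index = make_index()
        cwts = [cwt_group("SFB", 2000, 10_000.0, "a"),
                cwt_group("SFB", 2001, 10_000.0, "b")]
        totals = make_total_groups(cwts)
        params = make_params(
            index, M_value=0.1, M0={"a": 1.0, "b": 1.0},
            U={t.id: 5_000.0 for t in totals},
        )
        params.f[:] = 0.2
        by_id = {g.id: g for g in cwts + totals}
        states = [simulate_cohort(g, params, index, by_id) for g in totals]
        stratum = ("MONT", "summer", 2003, "troll")  # ages 3 and 2 present
        mu = expected_stock_catch(states, stratum, index)
        manual = 0.0
        for s in states:
            for t, step in enumerate(s.steps):
                if (step.season, step.year) == ("summer", 2003):
                    manual += s.catch[t, 0, 0]
        assert mu[0] == pytest.approx(manual)
        assert mu[1] == 0.0

    def test_expansion_identity_is_exact(self):
        assert expand_to_total_catch(50.0, 0.5) == 100.0
        assert expand_to_total_catch(50.0, 1.0) == 50.0
        assert expand_to_total_catch(0.0, 0.37) == 0.0
        mu_total = expand_to_total_catch(73.25, 0.41)
        assert mu_total * 0.41 == pytest.approx(73.25, rel=0, abs=0)
        with pytest.raises(ValueError):
            expand_to_total_catch(50.0, 0.0)

    def test_composition_sums_to_one_and_is_scale_invariant(self, rng):
        mu = rng.uniform(0, 10, size=4)
        total = mu.sum() / rng.uniform(0.3, 0.9)
        comp = expected_composition(mu, total)
        assert comp.sum() == pytest.approx(1.0)
        assert np.all(comp >= 0)
        scaled = expected_composition(10.0 * mu, 10.0 * total)
        assert np.allclose(comp, scaled)

    def test_composition_examples(self):
        comp = expected_composition(np.array([10.0, 10.0, 10.0, 10.0]), 50.0)
        assert np.allclose(comp, 0.2)
        comp = expected_composition(np.array([30.0, 0.0, 0.0, 0.0]), 60.0)
        assert np.allclose(comp, [0.5, 0, 0, 0, 0.5])
        exact = expected_composition(np.array([3.0, 7.0]), 10.0)
        assert exact[-1] == 0.0
        with pytest.raises(ValueError, match="below summed focal"):
            expected_composition(np.array([10.0, 10.0]), 15.0)

    def test_run_size_accumulates_fall_departures(self):
        index = make_index(ages=(2, 4), years=(2000, 2010))
        cwts = [cwt_group("SFB", 2000, 100_000.0, "a"),
                cwt_group("SFB", 2001, 100_000.0, "b")]
        totals = make_total_groups(cwts)
        params = make_params(
            index, M_value=0.05, m_young=0.4,
            M0={"a": 1.0, "b": 1.0}, U={t.id: 10_000.0 for t in totals},
        )
        by_id = {g.id: g for g in cwts + totals}
        states = [simulate_cohort(g, params, index, by_id) for g in totals]
        run_2004 = expected_run_size(states, "SFB", 2004)
        manual = sum(s.matured_by_year().get(2004, 0.0) for s in states)
        assert run_2004 == pytest.approx(manual)
        assert run_2004 > 0

    def test_terminal_only_maturation_toy_forward_simulation(self):
        # hand-simulated 2-age cohort with m(age 2) = 0: the run in the
        # terminal year is everything that survived to the terminal fall
        index = make_index(ages=(2, 3))
        cwt = cwt_group("SFB", 2000, 1000.0, "a")
        total = make_total_groups([cwt])[0]
        params = make_params(index, f_value=0.0, M_value=0.1, m_young=0.0,
                             M0={"a": 0.0}, U={total.id: 0.0})
        by_id = {cwt.id: cwt, total.id: total}
        states = [simulate_cohort(total, params, index, by_id)]
        assert expected_run_size(states, "SFB", 2002) == 0.0
        assert expected_run_size(states, "SFB", 2003) == pytest.approx(
            1000.0 * np.exp(-0.7)  # 7 steps at M = 0.1
        )
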