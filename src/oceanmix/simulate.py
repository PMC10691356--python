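"""Synthetic-data generation with known ground truth.

A :class:`Scenario` bundles a run configuration, a true parameter set, a
release plan, and sampling plans for each observation stream.  The
generator runs the cohort dynamics forward under the truth and draws every
observation from its likelihood's own family: negative-binomial tag
recoveries, per-fish multinomial GSI sampling (optionally pushed through a
misassignment confusion matrix before being summed into soft assignment
masses), lognormal run-size error, truncated-normal landings error, and
multinomial age counts.  A scenario's seed fully determines its output.

Three built-in scales emulate the structure of real coastal Chinook
monitoring data: ``toy`` (2 stocks x 4 regions x 6 years, single troll
fleet, desk-scale fitting), ``reduced`` (4 stocks x 8 regions x 10 years,
two fleets) and ``coastwide`` (4 stocks x 8 regions x 17 years with
release sizes spanning 9,000-3.5 million, no winter GSI, sparse northern
strata, and mild genetic misassignment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    CWT,
    TOTAL,
    ParameterSet,
    ReleaseGroup,
    expand_to_total_catch,
    expected_composition,
    expected_run_size,
    expected_stock_catch,
    make_total_groups,
    simulate_cohort,
)
from .data import ObservationBundle
from .index import ModelIndex, RunConfig
from .likelihoods import modeled_age_proportions

logger = logging.getLogger(__name__)

SCALES = ("toy", "reduced", "coastwide")


@dataclass
class Scenario:
    """A complete generative study design with known truth."""

    config: RunConfig
    truth: ParameterSet
    release_plan: list[ReleaseGroup]
    gsi_plan: list[tuple[tuple, int]]           # (stratum, n fish)
    landings_strata: list[tuple]
    age_plan: list[tuple[str, str, int, int]] = field(default_factory=list)
    misassignment: np.ndarray | None = None     # (K, K) row-stochastic
    #: GSI sampling noise: "multinomial" draws n fish from the expected
    #: composition (realistic emulation of dockside sampling); "zoid" draws
    #: the composition from the model's own zero-one-inflated Dirichlet
    #: (self-consistent with the likelihood, used for calibration studies)
    gsi_noise: str = "multinomial"
    seed: int = 0

    def __post_init__(self):
        index = self.config.index
        if self.gsi_noise not in ("multinomial", "zoid"):
            raise ValueError(f"unknown gsi_noise {self.gsi_noise!r}")
        if self.misassignment is not None:
            mis = np.asarray(self.misassignment, float)
            k = index.n_stocks + 1
            if mis.shape != (k, k) or not np.allclose(mis.sum(axis=1), 1.0):
                raise ValueError("misassignment must be row-stochastic (K, K)")
        for stratum, n in self.gsi_plan:
            self._check_stratum(stratum)
            if n <= 0:
                raise ValueError(f"GSI plan n must be > 0 at {stratum}")
        for stratum in self.landings_strata:
            self._check_stratum(stratum)

    def _check_stratum(self, stratum):
        index = self.config.index
        region, season, year, gear = stratum
        index.region_i(region), index.season_i(season)
        index.year_i(year), index.gear_i(gear)

    def with_truth(self, truth: ParameterSet) -> "Scenario":
        """Same design, different true parameters (keeps the data-side
        sampling fractions of the original truth)."""
        if truth.lam is None or truth.lam.shape != self.truth.lam.shape:
            truth = replace(truth, lam=self.truth.lam)
        return replace(self, truth=truth)

    def all_groups(self) -> list[ReleaseGroup]:
        return self.release_plan + make_total_groups(self.release_plan)


# ---------------------------------------------------------------------------
# Built-in scenarios
# ---------------------------------------------------------------------------

def _peaked_pi(index: ModelIndex, natal: Sequence[int], spread: float = 1.1,
               season_shift: dict | None = None) -> np.ndarray:
    """Distribution simplexes peaked near each stock's natal region, with a
    mild seasonal north/south displacement."""
    shift = season_shift or {"spring": 0.0, "summer": 0.4, "fall": 0.0, "winter": -0.4}
    L = index.n_regions
    pi = np.zeros((index.n_stocks, index.n_seasons, L))
    pos = np.arange(L, dtype=float)
    for r in range(index.n_stocks):
        for s, season in enumerate(index.seasons):
            center = natal[r] + shift[season]
            w = np.exp(-0.5 * ((pos - center) / spread) ** 2)
            pi[r, s] = w / w.sum()
    return pi


def _toy_scenario(seed: int) -> Scenario:
    rng = np.random.default_rng(seed)
    index = ModelIndex(
        stocks=("SFB", "KLT"),
        regions=("MONT", "SFB", "MEN", "NCA"),
        years=(2000, 2005),
        ages=(2, 3),
        gears=("troll",),
    )
    config = RunConfig(
        index=index,
        mcmc={"chains": 4, "warmup": 150, "retained": 400, "seed": 0},
        model_options={"f_by_year": False},
    )
    L, S, C, G = index.n_regions, index.n_seasons, index.n_years, index.n_gears

    # truth ------------------------------------------------------------
    pi = _peaked_pi(index, natal=[1, 3])
    season_f = {"spring": 0.10, "summer": 0.18, "fall": 0.14, "winter": 0.05}
    f = np.zeros((L, S, C, G))
    for s, season in enumerate(index.seasons):
        f[:, s, :, 0] = season_f[season] * (0.85 + 0.1 * np.arange(L))[:, None]
    lam = np.full((L, S, C, G), 0.25)
    m = np.array([[0.20, 1.0], [0.30, 1.0]])

    releases = []
    M0, delta, U = {}, {}, {}
    for stock in index.stocks:
        for brood in range(1998, 2004):
            gid = f"{stock}-{brood}"
            R = float(rng.integers(30_000, 120_000))
            releases.append(ReleaseGroup(gid, stock, brood, CWT, release_size=R))
            M0[gid] = float(rng.uniform(1.7, 2.3))
            entry = R * np.exp(-M0[gid])
            U[f"total:{stock}:{brood}"] = float(entry * rng.uniform(2.0, 6.0))

    p2bar = np.zeros((L, G))
    p2bar[:, 0] = np.array([1.6, 1.4, 1.1, 0.8])  # focal share declines northward
    sigma_p2 = 0.3
    gsi_plan = []
    p2 = {}
    for season in ("summer", "fall"):
        for region in index.regions:
            for year in index.year_list:
                stratum = (region, season, year, "troll")
                gsi_plan.append((stratum, int(rng.integers(100, 300))))
                l = index.region_i(region)
                p2[stratum] = float(
                    1.0 / (1.0 + np.exp(-rng.normal(p2bar[l, 0], sigma_p2)))
                )

    truth = ParameterSet(
        pi=pi, f=f, m=m, M=config.natural_mortality, lam=lam,
        M0=M0, delta=delta, U=U,
        tau=np.array([8.0]), phi=30.0,
        p2bar=p2bar, sigma_p2=sigma_p2, p2=p2,
        sigma_run=config.fixed_constants["sigma_run"],
        cv_land=config.fixed_constants["cv_land"],
    )

    landings_strata = [
        (region, season, year, "troll")
        for region in index.regions
        for season in index.seasons
        for year in index.year_list
    ]
    age_plan = [
        (stock, season, year, 100)
        for stock in index.stocks
        for season in ("summer", "fall")
        for year in index.year_list
    ]
    return Scenario(
        config=config, truth=truth, release_plan=releases,
        gsi_plan=gsi_plan, landings_strata=landings_strata,
        age_plan=age_plan, misassignment=None, seed=seed,
    )


def _coastal_scenario(seed: int, coastwide: bool) -> Scenario:
    rng = np.random.default_rng(seed)
    from .index import COASTAL_REGIONS, FOCAL_STOCKS

    years = (1998, 2014) if coastwide else (2000, 2009)
    index = ModelIndex(
        stocks=FOCAL_STOCKS,
        regions=COASTAL_REGIONS,
        years=years,
        ages=(2, 5),
        gears=("troll", "rec"),
    )
    config = RunConfig(index=index, model_options={"f_by_year": True})
    L, S, C, G = index.n_regions, index.n_seasons, index.n_years, index.n_gears

    pi = _peaked_pi(index, natal=[1.0, 2.3, 3.2, 4.0], spread=1.3)
    season_f = {"spring": 0.08, "summer": 0.15, "fall": 0.11, "winter": 0.015}
    f = np.zeros((L, S, C, G))
    for s, season in enumerate(index.seasons):
        base = season_f[season]
        f[:, s, :, 0] = base * rng.uniform(0.7, 1.3, size=(L, C))
        f[:, s, :, 1] = 0.5 * base * rng.uniform(0.7, 1.3, size=(L, C))
    lam = np.where(f > 0, 0.2, 0.0)

    A = index.n_ages
    m = np.zeros((index.n_stocks, A))
    m[:, :] = np.array([0.05, 0.25, 0.6, 1.0])[None, :]

    lo, hi = 9_000, 3_500_000
    releases, M0, U = [], {}, {}
    first_brood = years[0] - 2
    last_brood = years[1] - 2
    for stock in index.stocks:
        for brood in range(first_brood, last_brood + 1):
            gid = f"{stock}-{brood}"
            R = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            releases.append(ReleaseGroup(gid, stock, brood, CWT, release_size=R))
            M0[gid] = float(rng.uniform(1.5, 2.5))
            entry = R * np.exp(-M0[gid])
            U[f"total:{stock}:{brood}"] = float(entry * rng.uniform(1.5, 8.0))

    p2bar = np.zeros((L, G))
    p2bar[:, 0] = np.linspace(1.8, -0.8, L)   # focal share falls to the north
    p2bar[:, 1] = p2bar[:, 0] + 0.3
    sigma_p2 = 0.35

    gsi_seasons = ("spring", "summer", "fall")  # no winter GSI
    gsi_plan, p2 = [], {}
    for gear_i, gear in enumerate(index.gears):
        for season in gsi_seasons:
            for l, region in enumerate(index.regions):
                for year in index.year_list:
                    # voluntary sampling: sparse northern coverage
                    p_include = 0.85 if l < 5 else 0.3
                    if coastwide and gear == "rec" and year > years[0] + 4:
                        continue
                    if rng.random() > p_include:
                        continue
                    stratum = (region, season, year, gear)
                    gsi_plan.append((stratum, int(rng.integers(50, 500))))
                    p2[stratum] = float(
                        1.0 / (1.0 + np.exp(-rng.normal(p2bar[l, gear_i], sigma_p2)))
                    )

    truth = ParameterSet(
        pi=pi, f=f, m=m, M=config.natural_mortality, lam=lam,
        M0=M0, delta={}, U=U,
        tau=np.array([8.0, 6.0]), phi=25.0,
        p2bar=p2bar, sigma_p2=sigma_p2, p2=p2,
        sigma_run=config.fixed_constants["sigma_run"],
        cv_land=config.fixed_constants["cv_land"],
    )
    landings_strata = [
        (region, season, year, gear)
        for region in index.regions
        for season in index.seasons
        for year in index.year_list
        for gear in index.gears
    ]
    mis = None
    if coastwide:
        k = index.n_stocks + 1
        mis = np.full((k, k), 0.10 / (k - 1))
        np.fill_diagonal(mis, 0.90)
    return Scenario(
        config=config, truth=truth, release_plan=releases,
        gsi_plan=gsi_plan, landings_strata=landings_strata,
        age_plan=[], misassignment=mis, seed=seed,
    )


def default_scenario(scale: str = "toy", seed: int = 0) -> Scenario:
    """Built-in scenario at one of the scales in :data:`SCALES`."""
    if scale == "toy":
        return _toy_scenario(seed)
    if scale == "reduced":
        return _coastal_scenario(seed, coastwide=False)
    if scale == "coastwide":
        return _coastal_scenario(seed, coastwide=True)
    raise ValueError(f"unknown scale {scale!r}; choose from {SCALES}")


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _draw_zoid(rng: np.random.Generator, comp: np.ndarray, phi: float,
               n: float) -> np.ndarray:
    """Sample a composition from the zero-one-inflated Dirichlet: each
    category is structurally absent with probability (1 - p_k)^n,
    conditioned on a non-empty positive set; the positive components follow
    a Dirichlet with concentration phi * p_S / sum(p_S)."""
    comp = np.maximum(np.asarray(comp, float), 1e-10)
    comp = comp / comp.sum()
    theta0 = np.exp(n * np.log1p(-np.minimum(comp, 1 - 1e-12)))
    while True:
        positive = rng.random(len(comp)) >= theta0
        if positive.any():
            break
    y = np.zeros(len(comp))
    if positive.sum() == 1:
        y[positive] = 1.0
    else:
        w = comp[positive] / comp[positive].sum()
        y[positive] = rng.dirichlet(phi * w)
    return y

def simulate_dataset(scenario: Scenario) -> tuple[ObservationBundle, ParameterSet]:
    """Draw a complete observation bundle under the scenario's truth.

    Returns ``(bundle, truth)``.  Deterministic given ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    config, truth = scenario.config, scenario.truth
    index = config.index
    eq = config.model_options.get("catch_equation", "baranov")

    groups = scenario.all_groups()
    by_id = {g.id: g for g in groups}
    states = {g.id: simulate_cohort(g, truth, index, by_id, eq) for g in groups}
    total_states = [s for s in states.values() if s.group.group_class == TOTAL]

    # --- releases ------------------------------------------------------
    releases = pd.DataFrame(
        [
            {"group_id": g.id, "stock": g.stock, "brood_year": g.brood_year,
             "release_size": g.release_size}
            for g in scenario.release_plan
        ]
    )

    # --- CWT recoveries: one row per (group, sampled stratum) ----------
    cwt_rows = []
    tau = truth.tau if truth.tau is not None else np.full(index.n_gears, 20.0)
    for g in scenario.release_plan:
        st = states[g.id]
        for t, step in enumerate(st.steps):
            s, c = index.season_i(step.season), index.year_i(step.year)
            for l, region in enumerate(index.regions):
                for gi, gear in enumerate(index.gears):
                    lam = float(truth.lam[l, s, c, gi])
                    if lam <= 0:
                        continue
                    mean = lam * float(st.catch[t, l, gi])
                    t_g = float(tau[gi])
                    observed = (
                        rng.negative_binomial(t_g, t_g / (t_g + mean))
                        if mean > 0 else 0
                    )
                    cwt_rows.append(
                        {"group_id": g.id, "region": region, "season": step.season,
                         "year": step.year, "gear": gear,
                         "observed": int(observed), "lam": lam}
                    )
    from .data import (AGE_BASE_COLS, CWT_COLS, GSI_BASE_COLS,
                       LANDINGS_COLS, RUN_COLS)

    cwt_recoveries = pd.DataFrame(cwt_rows, columns=CWT_COLS)

    # --- GSI samples ----------------------------------------------------
    gsi_rows = []
    K = index.n_stocks + 1
    for stratum, n in scenario.gsi_plan:
        mu = expected_stock_catch(total_states, stratum, index)
        if mu.sum() <= 0:
            logger.warning("GSI stratum %s has zero expected catch; empty sample", stratum)
            continue
        p2 = truth.p2_for(index, stratum)
        comp = expected_composition(mu, expand_to_total_catch(float(mu.sum()), p2))
        if scenario.gsi_noise == "zoid":
            sums = n * _draw_zoid(rng, comp, truth.phi, n)
        else:
            fish = rng.multinomial(n, comp)      # true origin counts
            if scenario.misassignment is None:
                sums = fish.astype(float)
            else:
                # each fish's reported probability vector is its origin's
                # confusion-matrix row; summed mass per category is linear
                sums = fish @ scenario.misassignment
        region, season, year, gear = stratum
        row = {"region": region, "season": season, "year": year, "gear": gear,
               "n": int(n)}
        row.update({s: float(sums[i]) for i, s in enumerate(index.stocks)})
        row["other"] = float(sums[-1])
        gsi_rows.append(row)
    gsi_cols = GSI_BASE_COLS + list(index.stocks) + ['other']
    gsi_samples = pd.DataFrame(gsi_rows, columns=gsi_cols)

    # --- run sizes -------------------------------------------------------
    run_rows = []
    for stock in index.stocks:
        for year in index.year_list:
            run_hat = expected_run_size(total_states, stock, year)
            if run_hat <= 0:
                continue
            estimate = run_hat * np.exp(truth.sigma_run * rng.standard_normal())
            run_rows.append({"stock": stock, "year": year, "estimate": float(estimate)})
    run_sizes = pd.DataFrame(run_rows, columns=RUN_COLS)

    # --- landings --------------------------------------------------------
    land_rows = []
    for stratum in scenario.landings_strata:
        mu = expected_stock_catch(total_states, stratum, index)
        if mu.sum() <= 0:
            continue
        p2 = truth.p2_for(index, stratum)
        mu_total = expand_to_total_catch(float(mu.sum()), p2)
        sd = truth.cv_land * mu_total
        estimate = -1.0
        while estimate <= 0:  # truncate at zero (documented deviation)
            estimate = rng.normal(mu_total, sd)
        region, season, year, gear = stratum
        land_rows.append(
            {"region": region, "season": season, "year": year, "gear": gear,
             "estimate": float(estimate)}
        )
    landings = pd.DataFrame(land_rows, columns=LANDINGS_COLS)

    # --- age counts ------------------------------------------------------
    age_rows = []
    all_ages = index.age_list
    for stock, season, year, n_aged in scenario.age_plan:
        ages, p3 = modeled_age_proportions(total_states, stock, season, year)
        if len(ages) == 0:
            continue
        counts = rng.multinomial(n_aged, p3)
        row = {"stock": stock, "season": season, "year": year}
        row.update({f"age_{a}": 0 for a in all_ages})
        row.update({f"age_{a}": int(c) for a, c in zip(ages, counts)})
        age_rows.append(row)
    age_counts = pd.DataFrame(age_rows) if age_rows else None

    bundle = ObservationBundle(
        releases=releases, cwt_recoveries=cwt_recoveries,
        gsi_samples=gsi_samples, run_sizes=run_sizes,
        landings=landings, age_counts=age_counts,
    )
    bundle.require_valid(config)
    return bundle, truth


def write_fixture(bundle: ObservationBundle, truth: ParameterSet, directory,
                  config: RunConfig | None = None) -> list:
    """Write the observation tables and a truth file under ``directory``.

    Delegates to :mod:`oceanmix.io`; returns the written paths.
    """
    from . import io as _io

    return _io.write_bundle(bundle, directory, truth=truth, config=config)
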