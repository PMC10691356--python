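"""Deterministic forward dynamics of release groups.

Two kinds of release group are tracked through the same season-step
machinery:

* **CWT groups** — hatchery cohorts with a known release size.  Their ocean
  entry abundance at spring of age 2 is the release size discounted by the
  group's pre-age-2 instantaneous mortality plus a shared process deviation.
* **Total groups** — all smolts of a stock entering the ocean in one brood
  year, hatchery and natural origin together.  They enter at the summed
  expected abundance of the stock x brood-year's CWT groups (a hard lower
  bound) plus an estimated untagged abundance U.

Within each step, fish are allocated to regions by the stock's seasonal
distribution simplex, harvested and subject to natural mortality (Baranov
catch equation by default), and — in fall only — removed to freshwater by
maturation.  The resulting expected catches feed every observation
likelihood; the fall departures form expected run sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .index import ModelIndex, Step, season_step_iterator, MATURATION_SEASON

logger = logging.getLogger(__name__)

CWT = "cwt"
TOTAL = "total"


@dataclass(frozen=True)
class ReleaseGroup:
    """One tracked cohort (CWT or total); see module docstring."""

    id: str
    stock: str
    brood_year: int
    group_class: str  # "cwt" | "total"
    release_size: float | None = None  # known for cwt groups only
    linked_cwt_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.group_class not in (CWT, TOTAL):
            raise ValueError(f"unknown group class {self.group_class!r}")
        if self.group_class == CWT:
            if self.release_size is None or self.release_size <= 0:
                raise ValueError(f"CWT group {self.id}: release size must be > 0")


class ModelStructureError(RuntimeError):
    """A configuration/parameter combination that makes the model ill-posed."""


@dataclass
class ParameterSet:
    """Container for every estimated and fixed model parameter.

    Array axis conventions (all label-ordered by the ModelIndex):

    ``pi``     (stock, season, region) — spatial distribution simplex per row;
    ``f``      (region, season, year, gear) — fishery mortality rate;
    ``v``      (age, gear) — vulnerability multiplier in [0, 1];
    ``m``      (stock, age) — maturation probability, 1 at the terminal age;
    ``M``      (age,) — fixed per-step natural mortality;
    ``lam``    (region, season, year, gear) — CWT sampling fraction (data);
    ``tau``    (gear,) — CWT negative-binomial dispersion;
    ``p2bar``  (region, gear) — logit-scale mean focal proportion.

    ``M0``/``delta``/``U`` are keyed mappings (per CWT group, per stock x
    brood year, per total group).  ``p2`` holds latent focal proportions per
    stratum key ``(region, season, year, gear)``; strata missing from it fall
    back to ``inv_logit(p2bar)``.
    """

    pi: np.ndarray
    f: np.ndarray
    m: np.ndarray
    M: np.ndarray
    lam: np.ndarray
    v: np.ndarray | None = None
    M0: dict = field(default_factory=dict)
    delta: dict = field(default_factory=dict)
    U: dict = field(default_factory=dict)
    tau: np.ndarray | None = None
    phi: float = 20.0
    p2bar: np.ndarray | None = None
    sigma_p2: float = 0.5
    p2: dict = field(default_factory=dict)
    sigma_run: float = 0.3
    cv_land: float = 0.15
    sigma_delta: float = 0.5

    def validate(self, index: ModelIndex) -> list[str]:
        errors = []
        if self.pi.shape != (index.n_stocks, index.n_seasons, index.n_regions):
            errors.append(f"pi has shape {self.pi.shape}")
        else:
            sums = self.pi.sum(axis=-1)
            if np.any(self.pi < 0) or not np.allclose(sums, 1.0, atol=1e-8):
                errors.append("pi rows must be simplexes over regions")
        if np.any(self.f < 0):
            errors.append("fishing mortality rates must be >= 0")
        if np.any(self.m < 0) or np.any(self.m > 1):
            errors.append("maturation probabilities must lie in [0, 1]")
        if not np.allclose(self.m[:, -1], 1.0):
            errors.append("maturation at the terminal age must be 1")
        if np.any(self.lam < 0) or np.any(self.lam > 1):
            errors.append("sampling fractions must lie in [0, 1]")
        if self.phi <= 0:
            errors.append("phi must be > 0")
        if self.tau is not None and np.any(self.tau <= 0):
            errors.append("tau must be > 0")
        return errors

    def vulnerability(self, index: ModelIndex) -> np.ndarray:
        if self.v is None:
            return np.ones((index.n_ages, index.n_gears))
        return self.v

    def p2_for(self, index: ModelIndex, stratum: tuple) -> float:
        """Latent focal proportion for a stratum, falling back to the
        regional hierarchical mean when no latent value exists."""
        if stratum in self.p2:
            return float(self.p2[stratum])
        if self.p2bar is None:
            return 1.0
        l = index.region_i(stratum[0])
        g = index.gear_i(stratum[3])
        return float(1.0 / (1.0 + np.exp(-self.p2bar[l, g])))


@dataclass
class CohortState:
    """Expected trajectory of one release group over its season-steps.

    ``N[t]`` is the start-of-step ocean abundance; ``catch[t]`` the expected
    catch array (region, gear) in step ``t``; ``natural_deaths[t]`` the
    expected natural mortality removals; ``matured[t]`` the expected fall
    departures to freshwater (zero outside fall steps).
    """

    group: ReleaseGroup
    steps: list[Step]
    N: np.ndarray                      # (T+1,): start-of-step plus final survivors
    catch: np.ndarray                  # (T, L, G)
    natural_deaths: np.ndarray         # (T,)
    matured: np.ndarray                # (T,)
    truncated: bool = False

    def step_index(self, step: Step) -> int:
        return self.steps.index(step)

    def matured_by_year(self) -> dict[int, float]:
        """Expected freshwater departures keyed by calendar year."""
        out: dict[int, float] = {}
        for t, s in enumerate(self.steps):
            if self.matured[t] > 0 or s.season == MATURATION_SEASON:
                out[s.year] = out.get(s.year, 0.0) + float(self.matured[t])
        return out


# ---------------------------------------------------------------------------
# Entry abundance
# ---------------------------------------------------------------------------

def entry_abundance(
    group: ReleaseGroup,
    params: ParameterSet,
    groups_by_id: Mapping[str, ReleaseGroup] | None = None,
) -> float:
    """Expected ocean abundance at the spring step of age 2.

    CWT groups: ``R * exp(-(M0 + delta))`` where ``M0`` is the group's
    cumulative pre-age-2 instantaneous mortality and ``delta`` the process
    deviation shared by all releases of the same stock and brood year.
    Total groups: sum of the linked CWT groups' entry abundances plus the
    untagged abundance ``U`` — total entry can never fall below the tagged
    component.
    """
    if group.group_class == CWT:
        m0 = float(params.M0.get(group.id, 0.0))
        dev = float(params.delta.get((group.stock, group.brood_year), 0.0))
        return float(group.release_size) * float(np.exp(-(m0 + dev)))

    if not group.linked_cwt_ids:
        raise ModelStructureError(
            f"total group {group.id} has no linked CWT group; the CWT lower "
            "bound on total abundance cannot be formed"
        )
    if groups_by_id is None:
        raise ModelStructureError("groups_by_id required to resolve linked CWT groups")
    cwt_entry = 0.0
    for cid in group.linked_cwt_ids:
        linked = groups_by_id[cid]
        if linked.group_class != CWT:
            raise ModelStructureError(f"total group {group.id} links non-CWT group {cid}")
        cwt_entry += entry_abundance(linked, params)
    u = float(params.U.get(group.id, 0.0))
    if u < 0:
        raise ModelStructureError(f"untagged abundance U[{group.id}] must be >= 0")
    return cwt_entry + u


# ---------------------------------------------------------------------------
# One season-step
# ---------------------------------------------------------------------------

def step_abundance(
    N: float,
    step: Step,
    stock_i: int,
    params: ParameterSet,
    index: ModelIndex,
    catch_equation: str = "baranov",
) -> tuple[float, np.ndarray, float, float]:
    """Advance a cohort's abundance through one season-step.

    Returns ``(N_next, catch[L, G], natural_deaths, matured)``.

    Fish are first allocated among regions by the stock's seasonal simplex.
    Under the Baranov convention (default), fishing and natural mortality act
    simultaneously within the step: with total fishing mortality
    ``F_l = sum_g v[a,g] f[l,s,c,g]`` and natural mortality ``M``, the
    expected catch by gear is ``N pi_l (F_lg / Z_l) (1 - exp(-Z_l))`` with
    ``Z_l = F_l + M``, and survivors are ``N pi_l exp(-Z_l)``.  Under the
    sequential convention harvest precedes natural mortality:
    catch ``N pi_l (1 - exp(-F_l)) F_lg / F_l``, survival ``exp(-F_l - M)``.
    In fall, survivors mature (leave the ocean) with probability ``m[r, a]``.
    """
    if N < 0:
        raise ValueError("negative abundance")
    s = index.season_i(step.season)
    c = index.year_i(step.year)
    a = index.age_i(step.age)
    v = params.vulnerability(index)

    pi_row = params.pi[stock_i, s, :]                      # (L,)
    F_lg = v[a, :][None, :] * params.f[:, s, c, :]          # (L, G)
    if np.any(F_lg < 0):
        raise ValueError("negative fishing mortality rate")
    F_l = F_lg.sum(axis=1)                                  # (L,)
    M = float(params.M[a])
    alloc = N * pi_row                                      # (L,)

    if catch_equation == "baranov":
        Z = F_l + M
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(Z > 0, (1.0 - np.exp(-Z)) / np.where(Z > 0, Z, 1.0), 1.0)
        catch = alloc[:, None] * F_lg * frac[:, None]       # (L, G)
        survivors_l = alloc * np.exp(-Z)
        nat_deaths = float((alloc * M * frac).sum())
    elif catch_equation == "sequential":
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(F_l[:, None] > 0, F_lg / np.where(F_l[:, None] > 0, F_l[:, None], 1.0), 0.0)
        catch = alloc[:, None] * (1.0 - np.exp(-F_l))[:, None] * share
        survivors_l = alloc * np.exp(-(F_l + M))
        nat_deaths = float((alloc * np.exp(-F_l) * (1.0 - np.exp(-M))).sum())
    else:
        raise ValueError(f"unknown catch equation {catch_equation!r}")

    survivors = float(survivors_l.sum())
    matured = 0.0
    if step.season == MATURATION_SEASON:
        matured = survivors * float(params.m[stock_i, a])
    return survivors - matured, catch, nat_deaths, matured


def simulate_cohort(
    group: ReleaseGroup,
    params: ParameterSet,
    index: ModelIndex,
    groups_by_id: Mapping[str, ReleaseGroup] | None = None,
    catch_equation: str = "baranov",
) -> CohortState:
    """Run a release group forward through all its steps."""
    steps = season_step_iterator(index, group.brood_year)
    T = len(steps)
    r = index.stock_i(group.stock)
    N = np.zeros(T + 1)
    catch = np.zeros((T, index.n_regions, index.n_gears))
    nat = np.zeros(T)
    mat = np.zeros(T)
    N[0] = entry_abundance(group, params, groups_by_id)
    for t, step in enumerate(steps):
        N[t + 1], catch[t], nat[t], mat[t] = step_abundance(
            N[t], step, r, params, index, catch_equation
        )
    from .index import untruncated_step_count
    return CohortState(
        group=group, steps=steps, N=N, catch=catch,
        natural_deaths=nat, matured=mat,
        truncated=(T < untruncated_step_count(index)),
    )


# ---------------------------------------------------------------------------
# Derived expectations feeding the observation model
# ---------------------------------------------------------------------------

def expected_cwt_recoveries(
    state: CohortState, params: ParameterSet, index: ModelIndex
) -> dict[tuple, float]:
    """Expected tag recoveries per stratum: sampling fraction times catch.

    Returns a mapping ``(region, season, year, gear) -> lambda * C`` for the
    strata the cohort visits.  Strata with zero sampling fraction yield 0.
    """
    if np.any(params.lam < 0) or np.any(params.lam > 1):
        raise ValueError("sampling fractions must lie in [0, 1]")
    out: dict[tuple, float] = {}
    for t, step in enumerate(state.steps):
        s, c = index.season_i(step.season), index.year_i(step.year)
        for l, region in enumerate(index.regions):
            for g, gear in enumerate(index.gears):
                lam = params.lam[l, s, c, g]
                key = (region, step.season, step.year, gear)
                out[key] = out.get(key, 0.0) + float(lam * state.catch[t, l, g])
    return out


def expected_stock_catch(
    states: Sequence[CohortState],
    stratum: tuple,
    index: ModelIndex,
    stocks: Sequence[str] | None = None,
) -> np.ndarray:
    """Expected catch by focal stock in one (region, season, year, gear) cell.

    Sums each stock's *total*-group catches across all contributing ages.
    Returns a vector over ``stocks`` (default: the index's stock order).
    Cohorts missing for a contributing age simply contribute zero.
    """
    stocks = list(stocks if stocks is not None else index.stocks)
    region, season, year, gear = stratum
    l, g = index.region_i(region), index.gear_i(gear)
    mu = np.zeros(len(stocks))
    for state in states:
        if state.group.group_class != TOTAL:
            continue
        if state.group.stock not in stocks:
            continue
        for t, step in enumerate(state.steps):
            if step.season == season and step.year == year:
                mu[stocks.index(state.group.stock)] += state.catch[t, l, g]
    return mu


def expand_to_total_catch(mu_focal: float, p2: float) -> float:
    """Expand summed focal-stock catch to total catch across all stocks.

    ``mu_total = mu_focal / p2`` where ``p2`` is the expected proportion of
    the stratum's catch belonging to the focal stocks; the identity
    ``mu_total * p2 == mu_focal`` holds exactly.
    """
    if not (0.0 < p2 <= 1.0):
        raise ValueError(f"p2 must lie in (0, 1], got {p2}")
    return mu_focal / p2


def expected_composition(mu_stock: np.ndarray, mu_total: float) -> np.ndarray:
    """Expected composition (focal stocks..., other) of a stratum's catch.

    ``p1[r] = mu_stock[r] / mu_total``; the trailing component is the
    non-focal remainder.  The result sums to 1 and is invariant to common
    rescaling of all inputs.
    """
    mu_stock = np.asarray(mu_stock, float)
    focal = float(mu_stock.sum())
    if mu_total == 0.0 and focal == 0.0:
        # degenerate stratum: no expected catch at all
        k = len(mu_stock) + 1
        return np.full(k, 1.0 / k)
    if mu_total < focal * (1.0 - 1e-9) or mu_total <= 0:
        raise ValueError(
            f"total catch {mu_total} is below summed focal catch {focal}"
        )
    p = mu_stock / mu_total
    return np.concatenate([p, [max(0.0, 1.0 - p.sum())]])


def expected_run_size(
    states: Sequence[CohortState], stock: str, year: int
) -> float:
    """Expected freshwater returns of a stock in one year, summed over ages
    of its total release groups."""
    total = 0.0
    for state in states:
        if state.group.group_class != TOTAL or state.group.stock != stock:
            continue
        total += state.matured_by_year().get(year, 0.0)
    return total


def make_total_groups(
    cwt_groups: Sequence[ReleaseGroup],
) -> list[ReleaseGroup]:
    """Create one total release group per (stock, brood year) present among
    the CWT groups, linked to all that cell's CWT groups."""
    cells: dict[tuple, list[str]] = {}
    for grp in cwt_groups:
        if grp.group_class != CWT:
            raise ValueError(f"{grp.id} is not a CWT group")
        cells.setdefault((grp.stock, grp.brood_year), []).append(grp.id)
    return [
        ReleaseGroup(
            id=f"total:{stock}:{brood}",
            stock=stock,
            brood_year=brood,
            group_class=TOTAL,
            linked_cwt_ids=tuple(sorted(ids)),
        )
        for (stock, brood), ids in sorted(cells.items())
    ]
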