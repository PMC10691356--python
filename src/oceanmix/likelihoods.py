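"""Observation-model likelihood components.

Five observation streams link the deterministic cohort expectations to data:

* CWT recoveries — negative binomial around sampling-fraction-expanded
  expected catch, with per-gear overdispersion ``tau``;
* GSI stock compositions — zero-and-one-inflated Dirichlet (ZOID) around the
  expected proportional contribution of each focal stock, with concentration
  ``phi`` (smaller ``phi`` = more overdispersed = GSI down-weighted);
* focal-proportion samples — binomial counts of focal-stock assignments,
  with a logit-normal hierarchy across strata sharing a regional mean;
* run sizes — lognormal around expected freshwater returns with fixed
  log-scale SD;
* landings — normal around expected total catch with fixed CV;
* (optional) age compositions — multinomial against modeled age structure.

All functions return log densities; ``total_loglik`` accumulates them over
an observation bundle with per-component toggles, realizing the CWT-only,
CWT+GSI and CWT+GSI+Age model variants.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, xlogy

from .cohort import (
    CWT,
    TOTAL,
    CohortState,
    ParameterSet,
    ReleaseGroup,
    expand_to_total_catch,
    expected_composition,
    expected_run_size,
    expected_stock_catch,
    make_total_groups,
    simulate_cohort,
)
from .index import ModelIndex, RunConfig

logger = logging.getLogger(__name__)

#: Floor applied to expected counts so that an observed recovery against a
#: vanishing expectation stays finite (logged once per call site).
MEAN_FLOOR = 1e-8

#: Component names, in accumulation order.
COMPONENTS = ("cwt", "gsi", "p2", "p2_hier", "run_size", "landings", "age")

#: Component toggle sets realizing the named model variants.
#: The GSI block comprises both the ZOID composition likelihood and the
#: binomial focal-proportion term: the focal/other split of each sample
#: estimates the stratum's focal proportion directly, while the ZOID
#: scores the full composition.  The split thereby enters twice — a
#: deliberate constraint inherited from the source construction that
#: anchors the otherwise weakly identified per-stratum proportions (see
#: the methods note for the calibration consequences).
VARIANTS = {
    "cwt_only": frozenset({"cwt"}),
    "cwt_gsi": frozenset({"cwt", "gsi", "p2", "p2_hier", "run_size", "landings"}),
    "cwt_gsi_age": frozenset(
        {"cwt", "gsi", "p2", "p2_hier", "run_size", "landings", "age"}
    ),
}


def _logit(p):
    return np.log(p) - np.log1p(-p)


# ---------------------------------------------------------------------------
# CWT recoveries: negative binomial
# ---------------------------------------------------------------------------

def cwt_loglik(observed: float, expected: float, tau: float) -> float:
    """Negative-binomial log-pmf of an observed tag-recovery count.

    Parameterized by mean ``expected`` and dispersion ``tau`` (variance
    ``mu + mu^2 / tau``); ``tau -> inf`` recovers the Poisson.  Expected
    counts are floored at :data:`MEAN_FLOOR` so a zero prediction cannot
    produce ``-inf`` against a positive observation.
    """
    if observed < 0:
        raise ValueError(f"negative observed count {observed}")
    if tau <= 0:
        raise ValueError(f"dispersion tau must be > 0, got {tau}")
    if expected < 0:
        raise ValueError(f"negative expected count {expected}")
    if expected < MEAN_FLOOR:
        if observed > 0:
            logger.debug("flooring expected recoveries %g -> %g", expected, MEAN_FLOOR)
        expected = MEAN_FLOOR
    y, mu = float(observed), float(expected)
    return float(
        gammaln(y + tau) - gammaln(tau) - gammaln(y + 1.0)
        + tau * (np.log(tau) - np.log(tau + mu))
        + y * (np.log(mu) - np.log(tau + mu))
    )


# ---------------------------------------------------------------------------
# GSI compositions: zero-and-one-inflated Dirichlet
# ---------------------------------------------------------------------------

def zoid_zero_prob(p: np.ndarray, n: float) -> np.ndarray:
    """Structural-zero probability per category: ``(1 - p_k)^n``.

    A category is structurally absent from a sample of ``n`` fish if no fish
    lands in it; small samples therefore miss rare stocks more often.
    """
    return np.exp(n * np.log1p(-np.minimum(p, 1.0 - 1e-12)))


def zoid_pattern_logprob(zero_mask: np.ndarray, p: np.ndarray, n: float) -> float:
    """Log-probability of a zero-pattern, conditioned on a non-empty
    positive set (the all-zero pattern cannot be observed), so that pattern
    probabilities sum to 1 over the ``2^K - 1`` admissible patterns."""
    log_theta0 = n * np.log1p(-np.minimum(p, 1.0 - 1e-12))
    log_empty = float(log_theta0.sum())
    # log(1 - prod theta0), stable for prod near 0 and near 1
    log_norm = np.log1p(-np.exp(log_empty)) if log_empty < -1e-12 else -np.inf
    lp = float(
        np.sum(log_theta0[zero_mask])
        + np.sum(np.log(-np.expm1(np.minimum(log_theta0[~zero_mask], -1e-300))))
    )
    return lp - log_norm


def _dirichlet_logpdf(x: np.ndarray, conc: np.ndarray) -> float:
    return float(
        gammaln(conc.sum()) - gammaln(conc).sum() + ((conc - 1.0) * np.log(x)).sum()
    )


def zoid_loglik(y: np.ndarray, p: np.ndarray, phi: float, n: float) -> float:
    """Zero-and-one-inflated Dirichlet log-density of a composition ``y``.

    ``y`` lives on the closed simplex (exact zeros, and an exact one, are
    allowed); ``p`` is the strictly positive expected composition; ``phi``
    the concentration (overdispersion) scale; ``n`` the number of sampled
    fish driving the zero-pattern probabilities.

    The density factorizes into (i) the probability of the observed
    zero-pattern, with per-category absence probability ``(1 - p_k)^n``
    under independent thinning conditioned on a non-empty sample, and
    (ii) a Dirichlet density over the positive components, renormalized to
    their sub-simplex with concentration ``phi * p_S / sum(p_S)``.  A single
    positive component (one-inflation) carries no continuous density term.
    """
    y = np.asarray(y, float)
    p = np.asarray(p, float)
    if y.shape != p.shape:
        raise ValueError("y and p must have matching shapes")
    if np.any(y < 0) or abs(y.sum() - 1.0) > 1e-8:
        raise ValueError(f"y must lie on the closed simplex (sum={y.sum()!r})")
    if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("p must be a strictly positive simplex")
    if phi <= 0 or n <= 0:
        raise ValueError("phi and n must be > 0")

    zero = y == 0.0
    if zero.all():
        raise ValueError("y has no positive component")
    lp = zoid_pattern_logprob(zero, p, n)
    pos = ~zero
    if pos.sum() > 1:
        w = p[pos] / p[pos].sum()
        x = y[pos] / y[pos].sum()
        lp += _dirichlet_logpdf(x, phi * w)
    return lp


def gsi_loglik(
    stock_sums: np.ndarray,
    other_sum: float,
    n: float,
    composition: np.ndarray,
    phi: float,
) -> float:
    """GSI sample log-likelihood for one stratum.

    ``stock_sums`` are the summed per-fish assignment probabilities to each
    focal stock, ``other_sum`` the summed non-focal mass; together they
    partition the ``n`` sampled fish.  The observed composition
    ``y = (stock_sums, other) / n`` is compared to the model-expected
    composition through :func:`zoid_loglik`.
    """
    stock_sums = np.asarray(stock_sums, float)
    total = stock_sums.sum() + other_sum
    if abs(total - n) > 1e-6 * max(1.0, n):
        raise ValueError(
            f"GSI stock sums + other ({total}) do not partition n={n}"
        )
    y = np.concatenate([stock_sums, [other_sum]]) / n
    y = np.where(np.abs(y) < 1e-15, 0.0, y)
    y = y / y.sum()
    comp = np.asarray(composition, float)
    # expected compositions can carry exact zeros (e.g. no non-focal catch);
    # the ZOID density needs strictly positive p, so floor and renormalize.
    comp = np.maximum(comp, 1e-10)
    comp = comp / comp.sum()
    return zoid_loglik(y, comp, phi, n)


# ---------------------------------------------------------------------------
# Focal-proportion observations and hierarchy
# ---------------------------------------------------------------------------

def p2_loglik(k_focal: float, n: float, p2: float) -> float:
    """Binomial log-pmf of the summed focal-stock assignments among ``n``
    sampled fish.  Soft (non-integer) sums are rounded to the nearest count.
    """
    if not (0 <= k_focal <= n):
        raise ValueError(f"k_focal={k_focal} outside [0, n={n}]")
    if not (0.0 < p2 < 1.0):
        raise ValueError(f"p2 must lie in (0, 1), got {p2}")
    k = float(np.round(k_focal))
    n = float(np.round(n))
    return float(
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + xlogy(k, p2) + xlogy(n - k, 1.0 - p2)
    )


def p2_hierarchical_loglik(
    p2_values: Mapping[tuple, float] | Sequence[float],
    p2bar: float | np.ndarray,
    sigma_p2: float,
    region_of: Callable[[tuple], int] | None = None,
) -> float:
    """Logit-normal hierarchy across strata: ``logit(p2) ~ N(p2bar_l, sigma)``.

    ``p2bar`` is the logit-scale regional mean (scalar, or an array indexed
    by ``region_of(stratum_key)``).  Strata lacking GSI data borrow strength
    through this shared distribution.
    """
    if sigma_p2 <= 0:
        raise ValueError("sigma_p2 must be > 0")
    if isinstance(p2_values, Mapping):
        items = list(p2_values.items())
        vals = np.array([v for _, v in items], float)
        if region_of is not None and np.ndim(p2bar) > 0:
            means = np.array([np.asarray(p2bar)[region_of(k)] for k, _ in items])
        else:
            means = np.full(len(vals), float(np.asarray(p2bar).reshape(-1)[0]))
    else:
        vals = np.asarray(p2_values, float)
        means = np.broadcast_to(np.asarray(p2bar, float), vals.shape)
    if np.any(vals <= 0) or np.any(vals >= 1):
        raise ValueError("p2 values must lie strictly inside (0, 1)")
    z = _logit(vals)
    return float(
        np.sum(-0.5 * np.log(2 * np.pi) - np.log(sigma_p2)
               - 0.5 * ((z - means) / sigma_p2) ** 2)
    )


# ---------------------------------------------------------------------------
# Run sizes, landings, ages
# ---------------------------------------------------------------------------

def runsize_loglik(observed: float, expected: float, sigma_run: float) -> float:
    """Lognormal log-density of an observed run-size estimate: the log of the
    observation is normal around the log expected freshwater return, with
    fixed SD ``sigma_run``.  Depends only on the log-ratio, hence scale-free.
    """
    if observed <= 0 or expected <= 0:
        raise ValueError("run sizes must be > 0")
    if sigma_run <= 0:
        raise ValueError("sigma_run must be > 0")
    z = (np.log(observed) - np.log(expected)) / sigma_run
    return float(-0.5 * np.log(2 * np.pi) - np.log(sigma_run) - 0.5 * z * z)


def landings_loglik(observed: float, expected: float, cv_land: float) -> float:
    """Normal log-density of observed landings with SD ``cv_land * expected``."""
    if cv_land <= 0:
        raise ValueError("cv_land must be > 0")
    if expected <= 0:
        raise ValueError("expected landings must be > 0")
    sd = cv_land * expected
    z = (observed - expected) / sd
    return float(-0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * z * z)


def age_loglik(A: np.ndarray, p3: np.ndarray) -> float:
    """Multinomial log-pmf of aged-fish counts ``A`` against modeled age
    proportions ``p3`` over the ages present in the season."""
    A = np.asarray(A, float)
    p3 = np.asarray(p3, float)
    if np.any(A < 0):
        raise ValueError("age counts must be >= 0")
    if A.shape != p3.shape:
        raise ValueError("A and p3 must have matching length")
    if np.any((p3 == 0) & (A > 0)):
        raise ValueError("age counts observed for an age absent from the support")
    n = A.sum()
    return float(
        gammaln(n + 1) - gammaln(A + 1).sum() + xlogy(A, np.maximum(p3, 1e-300)).sum()
    )


# ---------------------------------------------------------------------------
# Full accumulation
# ---------------------------------------------------------------------------

def modeled_age_proportions(
    states: Sequence[CohortState], stock: str, season: str, year: int
) -> tuple[list[int], np.ndarray]:
    """Modeled age composition of a stock's ocean abundance in one season
    and year: start-of-step abundances of its total groups, normalized over
    the ages present.  Returns ``(ages, p3)``."""
    by_age: dict[int, float] = {}
    for state in states:
        if state.group.group_class != TOTAL or state.group.stock != stock:
            continue
        for t, step in enumerate(state.steps):
            if step.season == season and step.year == year:
                by_age[step.age] = by_age.get(step.age, 0.0) + float(state.N[t])
    ages = sorted(by_age)
    if not ages:
        return [], np.array([])
    vals = np.array([by_age[a] for a in ages])
    return ages, vals / vals.sum()


def total_loglik(
    params: ParameterSet,
    data,
    config: RunConfig,
    components: Iterable[str] | str = "cwt_gsi",
    log_prior: Callable[[ParameterSet], float] | None = None,
    states: Mapping[str, CohortState] | None = None,
) -> float:
    """Log-posterior kernel: toggled component log-likelihoods plus priors.

    ``components`` is either a variant name from :data:`VARIANTS` or an
    iterable of component names from :data:`COMPONENTS`.  ``data`` is an
    :class:`~oceanmix.data.ObservationBundle`.  This is the reference
    (row-by-row) accumulation; the batched kernel used for sampling is
    checked against it.
    """
    if isinstance(components, str):
        try:
            active = VARIANTS[components]
        except KeyError:
            raise ValueError(f"unknown variant {components!r}") from None
    else:
        active = frozenset(components)
        unknown = active - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components {sorted(unknown)}")

    index = config.index
    total = 0.0 if log_prior is None else float(log_prior(params))

    if not active:
        return total

    if states is None:
        states = simulate_bundle_cohorts(params, data, config)
    state_list = list(states.values())

    if "cwt" in active:
        tau = params.tau if params.tau is not None else np.full(index.n_gears, 20.0)
        for row in data.cwt_recoveries.itertuples(index=False):
            st = states[row.group_id]
            lam = float(row.lam)
            if not (0.0 <= lam <= 1.0):
                raise ValueError(f"sampling fraction {lam} outside [0, 1]")
            l, g = index.region_i(row.region), index.gear_i(row.gear)
            expected = 0.0
            for t, step in enumerate(st.steps):
                if step.season == row.season and step.year == row.year:
                    expected += float(st.catch[t, l, g])
            total += cwt_loglik(row.observed, lam * expected, float(tau[g]))

    needs_mu = active & {"gsi", "landings"}
    if needs_mu or "age" in active or "run_size" in active:
        pass  # states already built

    if "gsi" in active or "p2" in active:
        for row in data.gsi_samples.itertuples(index=False):
            stratum = (row.region, row.season, row.year, row.gear)
            sums = np.array([getattr(row, s) for s in index.stocks], float)
            if "gsi" in active:
                mu = expected_stock_catch(state_list, stratum, index)
                p2 = params.p2_for(index, stratum)
                mu_total = expand_to_total_catch(float(mu.sum()), p2)
                comp = expected_composition(mu, mu_total)
                total += gsi_loglik(sums, float(row.other), float(row.n), comp, params.phi)
            if "p2" in active:
                p2 = params.p2_for(index, stratum)
                total += p2_loglik(float(sums.sum()), float(row.n), p2)

    if "p2_hier" in active and params.p2:
        if params.p2bar is None:
            raise ValueError("p2 hierarchy requires p2bar")
        p2bar = np.asarray(params.p2bar, float)
        if p2bar.ndim == 1:
            p2bar = p2bar[:, None]  # (L, 1)
        items = sorted(params.p2.items())
        vals = [v for _, v in items]
        means = np.array(
            [p2bar[index.region_i(k[0]), index.gear_i(k[3]) % p2bar.shape[1]]
             for k, _ in items]
        )
        total += p2_hierarchical_loglik(vals, means, params.sigma_p2)

    if "run_size" in active:
        for row in data.run_sizes.itertuples(index=False):
            expected = expected_run_size(state_list, row.stock, int(row.year))
            if expected <= 0:
                expected = MEAN_FLOOR
            total += runsize_loglik(float(row.estimate), expected, params.sigma_run)

    if "landings" in active:
        for row in data.landings.itertuples(index=False):
            stratum = (row.region, row.season, row.year, row.gear)
            mu = expected_stock_catch(state_list, stratum, index)
            p2 = params.p2_for(index, stratum)
            mu_total = expand_to_total_catch(float(mu.sum()), p2)
            if mu_total <= 0:
                mu_total = MEAN_FLOOR
            total += landings_loglik(float(row.estimate), mu_total, params.cv_land)

    if "age" in active and data.age_counts is not None and len(data.age_counts):
        age_cols = [c for c in data.age_counts.columns if c.startswith("age_")]
        for row in data.age_counts.itertuples(index=False):
            ages, p3 = modeled_age_proportions(
                state_list, row.stock, row.season, int(row.year)
            )
            counts, support = [], []
            for col in age_cols:
                a = int(col.split("_")[1])
                cnt = float(getattr(row, col))
                if a in ages:
                    counts.append(cnt)
                    support.append(p3[ages.index(a)])
                elif cnt > 0:
                    raise ValueError(
                        f"age counts present for age {a} absent from "
                        f"({row.stock}, {row.season}, {row.year})"
                    )
            if counts:
                total += age_loglik(np.array(counts), np.array(support))

    if not np.isfinite(total):
        logger.error("non-finite log posterior (components=%s)", sorted(active))
    return float(total)


def simulate_bundle_cohorts(
    params: ParameterSet, data, config: RunConfig
) -> dict[str, CohortState]:
    """Forward-simulate every release group referenced by a bundle."""
    groups = data.release_groups()
    by_id = {g.id: g for g in groups}
    eq = config.model_options.get("catch_equation", "baranov")
    return {
        g.id: simulate_cohort(g, params, config.index, by_id, eq) for g in groups
    }
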