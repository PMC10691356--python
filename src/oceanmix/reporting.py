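"""Derived posterior summaries: seasonal distributions, stock abundances,
proportional contributions, and model-variant comparisons."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import TOTAL, simulate_cohort
from .data import ObservationBundle
from .index import RunConfig
from .inference import PosteriorDraws
from .model import ParameterSpec, PosteriorKernel

logger = logging.getLogger(__name__)


def summarize_distribution(draws: PosteriorDraws,
                           level: float = 0.95) -> pd.DataFrame:
    """Posterior median and credible interval of every spatial-distribution
    component ``pi[stock, season, region]``.

    Intervals are marginal (component-wise) quantiles, so the medians of a
    (stock, season) row need not sum to 1 even though every single draw does.
    """
    names = draws.select("pi[")
    if not names:
        raise KeyError("no pi[...] parameters found in draws")
    lo_q, hi_q = 0.5 - level / 2.0, 0.5 + level / 2.0
    rows = []
    for name in names:
        stock, season, region = name[3:-1].split(",")
        vals = draws.get(name).ravel()
        lo, med, hi = np.quantile(vals, [lo_q, 0.5, hi_q])
        rows.append(
            {"stock": stock, "season": season, "region": region,
             "median": med, "lo": lo, "hi": hi}
        )
    return pd.DataFrame(rows)


def summarize_abundance(
    draws: PosteriorDraws,
    config: RunConfig,
    data: ObservationBundle,
    years: Sequence[int] | None = None,
    level: float = 0.95,
    max_draws: int = 200,
) -> pd.DataFrame:
    """Posterior summaries of start-of-season ocean abundance by stock,
    region, season, and year (pre-fishing within the season).

    Each retained draw is pushed through the cohort forward pass; total-group
    abundances at each step are allocated to regions by that draw's ``pi``
    and summed over ages, then summarized by marginal quantiles.  Also
    reports each stock's proportional contribution to the stratum total,
    which sums to 1 across stocks within every draw.
    """
    index = config.index
    if years is None:
        years = index.year_list
    for y in years:
        index.year_i(y)  # raises IndexError when outside range

    if draws.unconstrained is None:
        raise ValueError("draws lack unconstrained values needed for the forward pass")
    kernel = PosteriorKernel(config, data, components=set())
    spec = kernel.spec
    flat = draws.unconstrained.reshape(-1, spec.dim)
    step = max(1, len(flat) // max_draws)
    subset = flat[::step]

    groups = data.release_groups()
    by_id = {g.id: g for g in groups}
    totals = [g for g in groups if g.group_class == TOTAL]
    eq = config.model_options.get("catch_equation", "baranov")

    R, L, S = index.n_stocks, index.n_regions, index.n_seasons
    abun = np.zeros((len(subset), R, L, S, len(years)))
    ypos = {y: i for i, y in enumerate(years)}
    for di, x in enumerate(subset):
        ps = spec.to_parameter_set(x)
        for grp in totals:
            state = simulate_cohort(grp, ps, index, by_id, eq)
            r = index.stock_i(grp.stock)
            for t, stp in enumerate(state.steps):
                if stp.year not in ypos:
                    continue
                s = index.season_i(stp.season)
                abun[di, r, :, s, ypos[stp.year]] += state.N[t] * ps.pi[r, s, :]

    lo_q, hi_q = 0.5 - level / 2.0, 0.5 + level / 2.0
    totals_strat = abun.sum(axis=1, keepdims=True)          # across stocks
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(totals_strat > 0, abun / totals_strat, np.nan)

    rows = []
    for r, stock in enumerate(index.stocks):
        for l, region in enumerate(index.regions):
            for s, season in enumerate(index.seasons):
                for yi, year in enumerate(years):
                    a = abun[:, r, l, s, yi]
                    p = props[:, r, l, s, yi]
                    lo, med, hi = np.quantile(a, [lo_q, 0.5, hi_q])
                    rows.append(
                        {"stock": stock, "region": region, "season": season,
                         "year": year, "median": med, "lo": lo, "hi": hi,
                         "prop_median": float(np.nanmedian(p))}
                    )
    return pd.DataFrame(rows)


def compare_variants(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Interval-overlap table between two distribution summaries.

    For each (stock, season, region): whether the two 95% intervals overlap
    (touching endpoints count as overlapping — closed-interval convention)
    and the sign of the median shift ``b - a``.  Swapping the arguments
    flips every shift sign.
    """
    key = ["stock", "season", "region"]
    for df, label in ((a, "a"), (b, "b")):
        missing = [c for c in key + ["median", "lo", "hi"] if c not in df.columns]
        if missing:
            raise KeyError(f"summary {label} missing columns {missing}")
    merged = a.merge(b, on=key, suffixes=("_a", "_b"), how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", key].values.tolist()
        raise KeyError(f"summaries do not share index sets; e.g. {bad[:3]}")
    merged["overlap"] = (merged.lo_a <= merged.hi_b) & (merged.lo_b <= merged.hi_a)
    merged["shift"] = np.sign(merged.median_b - merged.median_a).astype(int)
    return merged[key + ["median_a", "lo_a", "hi_a",
                         "median_b", "lo_b", "hi_b", "overlap", "shift"]]
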