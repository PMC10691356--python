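"""Discrete model structure: stocks, regions, seasons, ages, years, gears.

Everything downstream (cohort dynamics, likelihoods, inference, reporting)
indexes into the sets defined here.  Regions are ordered labels running
south to north; seasons are abstract ordered labels with a fixed within-year
step order (spring -> summer -> fall -> winter) — no calendar months enter
any computation.  Cohorts enter the model at the spring step of ocean age 2
and leave it, at the latest, at the fall step of the terminal age, where
maturation probability is fixed at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: Within-year step order.  Winter is the last step of a model year; fall is
#: the unique maturation season.
SEASON_ORDER: tuple[str, ...] = ("spring", "summer", "fall", "winter")
MATURATION_SEASON = "fall"

#: Region codes of the full coastal configuration, ordered south -> north.
COASTAL_REGIONS: tuple[str, ...] = (
    "MONT", "SFB", "MEN", "NCA", "SOR", "NOR", "COL", "WAC",
)
#: The four focal fall-run stock codes.
FOCAL_STOCKS: tuple[str, ...] = ("SFB", "CAC", "KLT", "NCASOR")

DEFAULT_GEARS: tuple[str, ...] = ("troll", "rec")


class ConfigError(ValueError):
    """Raised when a configuration fails validation; message lists all errors."""


@dataclass(frozen=True)
class Step:
    """One season-step in a cohort's life: (calendar year, season, ocean age)."""

    year: int
    season: str
    age: int

    def __iter__(self):
        return iter((self.year, self.season, self.age))


@dataclass(frozen=True)
class ModelIndex:
    """Index sets shared by all model components.

    Parameters
    ----------
    stocks : ordered stock codes.
    regions : ordered region codes, index 0 = southernmost.
    years : inclusive calendar-year range ``(first, last)``.
    ages : inclusive ocean-age range ``(first, last)``; the first age must
        be 2 (cohorts enter at spring of age 2).
    gears : fleet codes.
    seasons : season labels in step order; fixed to the standard cycle.
    """

    stocks: tuple[str, ...]
    regions: tuple[str, ...]
    years: tuple[int, int]
    ages: tuple[int, int] = (2, 5)
    gears: tuple[str, ...] = DEFAULT_GEARS
    seasons: tuple[str, ...] = SEASON_ORDER

    def __post_init__(self):
        errors = self.validate()
        if errors:
            raise ConfigError("invalid ModelIndex: " + "; ".join(errors))

    def validate(self) -> list[str]:
        errors = []
        for name in ("stocks", "regions", "gears"):
            vals = getattr(self, name)
            if len(vals) == 0:
                errors.append(f"{name} is empty")
            if len(set(vals)) != len(vals):
                errors.append(f"{name} contains duplicates: {vals}")
        if not (2 <= len(self.regions) <= 8):
            errors.append(f"need 2..8 regions, got {len(self.regions)}")
        if self.seasons != SEASON_ORDER:
            errors.append(f"seasons must be {SEASON_ORDER} in step order")
        if self.years[0] > self.years[1]:
            errors.append(f"empty year range {self.years}")
        if self.ages[0] != 2:
            errors.append(f"ages must start at 2 (ocean entry), got {self.ages[0]}")
        if self.ages[1] < self.ages[0]:
            errors.append(f"empty age range {self.ages}")
        return errors

    # -- cardinalities ------------------------------------------------------
    @property
    def n_stocks(self) -> int:
        return len(self.stocks)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_seasons(self) -> int:
        return len(self.seasons)

    @property
    def n_gears(self) -> int:
        return len(self.gears)

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    @property
    def age_list(self) -> list[int]:
        return list(range(self.ages[0], self.ages[1] + 1))

    @property
    def n_ages(self) -> int:
        return self.ages[1] - self.ages[0] + 1

    @property
    def terminal_age(self) -> int:
        return self.ages[1]

    # -- label -> position lookups -----------------------------------------
    def stock_i(self, code: str) -> int:
        return self.stocks.index(code)

    def region_i(self, code: str) -> int:
        return self.regions.index(code)

    def season_i(self, code: str) -> int:
        return self.seasons.index(code)

    def year_i(self, year: int) -> int:
        if not (self.years[0] <= year <= self.years[1]):
            raise IndexError(f"year {year} outside configured range {self.years}")
        return year - self.years[0]

    def age_i(self, age: int) -> int:
        if not (self.ages[0] <= age <= self.ages[1]):
            raise IndexError(f"age {age} outside configured range {self.ages}")
        return age - self.ages[0]

    def gear_i(self, code: str) -> int:
        return self.gears.index(code)

    def to_dict(self) -> dict[str, Any]:
        return {
            "stocks": list(self.stocks),
            "regions": list(self.regions),
            "years": list(self.years),
            "ages": list(self.ages),
            "gears": list(self.gears),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelIndex":
        return cls(
            stocks=tuple(d["stocks"]),
            regions=tuple(d["regions"]),
            years=tuple(d["years"]),
            ages=tuple(d.get("ages", (2, 5))),
            gears=tuple(d.get("gears", DEFAULT_GEARS)),
        )


def season_step_iterator(index: ModelIndex, brood_year: int) -> list[Step]:
    """Ordered life-history steps of a cohort with the given brood year.

    The cohort appears at the spring step of ocean age 2, in calendar year
    ``brood_year + 2`` (model-year anchoring: calendar year = brood year +
    age; the age increments at the spring step).  The final step is the fall
    of the terminal age — the winter of the terminal year is never reached
    because terminal maturation removes all remaining fish in fall.  Steps
    whose calendar year falls outside the configured year range are dropped
    with a warning.

    Returns the (possibly truncated) list of :class:`Step`.
    """
    first_year = brood_year + index.ages[0]
    if first_year > index.years[1]:
        raise IndexError(
            f"brood year {brood_year}: cohort enters the ocean in {first_year}, "
            f"after the configured year range {index.years}"
        )
    steps: list[Step] = []
    for age in index.age_list:
        year = brood_year + age
        seasons = index.seasons if age < index.terminal_age else index.seasons[:3]
        for season in seasons:
            steps.append(Step(year=year, season=season, age=age))
    kept = [s for s in steps if index.years[0] <= s.year <= index.years[1]]
    if len(kept) < len(steps):
        key = (brood_year, index.years)
        if key not in _warned_truncations:
            _warned_truncations.add(key)
            logger.warning(
                "cohort with brood year %d truncated to the year range %s: "
                "%d of %d steps kept", brood_year, index.years,
                len(kept), len(steps),
            )
    return kept


#: truncation warnings are emitted once per (brood year, year range)
_warned_truncations: set = set()


def untruncated_step_count(index: ModelIndex) -> int:
    """Number of steps for a cohort fully inside the year range."""
    return 4 * (index.terminal_age - 2) + 3


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

DEFAULT_MCMC = {"chains": 6, "warmup": 400, "retained": 1400, "seed": 0}

#: Per-step instantaneous natural mortality by ocean age (placeholder values,
#: overridable from config).
DEFAULT_M_BY_AGE = {2: 0.1031, 3: 0.0561, 4: 0.0431, 5: 0.0431}

DEFAULT_CONSTANTS = {
    "natural_mortality": DEFAULT_M_BY_AGE,
    "sigma_run": 0.3,
    "cv_land": 0.15,
    "sigma_delta": 0.5,
}

#: Default prior hyperparameters.  Keys are parameter block names; values are
#: interpreted by the model assembly.  Rates are modeled on the log scale,
#: probabilities on the logit scale.
DEFAULT_PRIORS = {
    "pi": {"dist": "dirichlet", "alpha": 1.0},
    "log_M0": {"dist": "normal", "mu": 0.7, "sigma": 0.5},
    "delta": {"dist": "normal", "mu": 0.0, "sigma": 0.5},
    "log_U": {"dist": "normal", "mu": 13.0, "sigma": 1.5},
    "log_f": {"dist": "normal", "mu": -1.6, "sigma": 0.7},
    "logit_v": {"dist": "normal", "mu": 0.0, "sigma": 2.0},
    "logit_m": {"dist": "normal", "mu": 0.0, "sigma": 1.0},
    "tau": {"dist": "gamma", "shape": 2.0, "rate": 0.1},
    "phi": {"dist": "gamma", "shape": 2.0, "rate": 0.1},
    "p2bar": {"dist": "normal", "mu": 0.5, "sigma": 0.7},
    "sigma_p2": {"dist": "half_normal", "sigma": 0.5},
}

DEFAULT_MODEL_OPTIONS = {
    # one fishing-mortality rate per (region, season, year, gear) as in the
    # full configuration; False shares rates across years.
    "f_by_year": True,
    # estimate per-group pre-age-2 deviations / age vulnerabilities; when
    # False they are fixed at 0 / 1 respectively.
    "estimate_delta": False,
    "estimate_v": False,
    # "baranov" (simultaneous F and M within a step) or "sequential"
    # (harvest first, then natural mortality).
    "catch_equation": "baranov",
}


@dataclass
class RunConfig:
    """Validated run configuration: index sets, fixed constants, priors, MCMC.

    ``fixed_constants`` holds quantities the model never estimates: the
    per-step natural mortality schedule ``natural_mortality`` (by age), the
    run-size log-SD ``sigma_run``, the landings CV ``cv_land``, and the
    optional fixed age-composition table ``p3_fixed`` used by the synthetic
    age-structure variant (rows over ages, summing to 1, per stock class and
    season).
    """

    index: ModelIndex
    fixed_constants: dict[str, Any] = field(default_factory=lambda: dict(DEFAULT_CONSTANTS))
    mcmc: dict[str, Any] = field(default_factory=lambda: dict(DEFAULT_MCMC))
    priors: dict[str, Any] = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PRIORS.items()})
    model_options: dict[str, Any] = field(default_factory=lambda: dict(DEFAULT_MODEL_OPTIONS))
    io: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        errors = self.validate()
        if errors:
            raise ConfigError("invalid RunConfig: " + "; ".join(errors))

    def validate(self) -> list[str]:
        errors: list[str] = []
        for key, default in DEFAULT_MCMC.items():
            self.mcmc.setdefault(key, default)
        for key, default in DEFAULT_CONSTANTS.items():
            self.fixed_constants.setdefault(key, default)
        for key, default in DEFAULT_MODEL_OPTIONS.items():
            self.model_options.setdefault(key, default)
        for key, default in DEFAULT_PRIORS.items():
            self.priors.setdefault(key, dict(default))

        if self.mcmc["chains"] < 1:
            errors.append("mcmc.chains must be >= 1")
        if self.mcmc["warmup"] < 0 or self.mcmc["retained"] < 1:
            errors.append("mcmc.warmup must be >= 0 and mcmc.retained >= 1")

        nm = self.fixed_constants["natural_mortality"]
        for age in self.index.age_list:
            if age not in nm:
                errors.append(f"natural_mortality missing age {age}")
            elif nm[age] <= 0:
                errors.append(f"natural_mortality[{age}] must be > 0")
        for key in ("sigma_run", "cv_land", "sigma_delta"):
            if self.fixed_constants[key] <= 0:
                errors.append(f"fixed constant {key} must be > 0")

        p3 = self.fixed_constants.get("p3_fixed")
        if p3 is not None:
            for klass, by_season in p3.items():
                for season, row in by_season.items():
                    row = np.asarray(list(row.values()) if isinstance(row, dict) else row, float)
                    if np.any(row < 0) or abs(row.sum() - 1.0) > 1e-6:
                        errors.append(
                            f"p3_fixed[{klass}][{season}] is not a probability "
                            f"simplex (sum={row.sum():.6f})"
                        )
        if self.model_options["catch_equation"] not in ("baranov", "sequential"):
            errors.append(f"unknown catch_equation {self.model_options['catch_equation']!r}")
        return errors

    @property
    def natural_mortality(self) -> np.ndarray:
        """Fixed per-step natural mortality, shape (n_ages,) following age order."""
        nm = self.fixed_constants["natural_mortality"]
        return np.array([nm[a] for a in self.index.age_list], float)

    def to_dict(self) -> dict[str, Any]:
        return {
            "index": self.index.to_dict(),
            "constants": _plain(self.fixed_constants),
            "mcmc": _plain(self.mcmc),
            "priors": _plain(self.priors),
            "model_options": _plain(self.model_options),
            "io": _plain(self.io),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        missing = [k for k in ("index",) if k not in d]
        if missing:
            raise ConfigError(f"configuration missing required keys: {missing}")
        idx = d["index"]
        for key in ("stocks", "regions", "years"):
            if key not in idx:
                raise ConfigError(f"configuration missing required key: index.{key}")
        constants = dict(d.get("constants", {}))
        if "natural_mortality" in constants:
            constants["natural_mortality"] = {
                int(k): float(v) for k, v in constants["natural_mortality"].items()
            }
        return cls(
            index=ModelIndex.from_dict(idx),
            fixed_constants=constants,
            mcmc=dict(d.get("mcmc", {})),
            priors={k: dict(v) for k, v in d.get("priors", {}).items()},
            model_options=dict(d.get("model_options", {})),
            io=dict(d.get("io", {})),
        )


def _plain(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays so YAML round-trips cleanly."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises :class:`ConfigError` naming every missing key or failed validation.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return RunConfig.from_dict(raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
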