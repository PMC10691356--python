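"""Observation bundle: the tabular datasets the model consumes.

Six tables, all plain CSV on disk (see :mod:`oceanmix.io`):

``releases``        group_id, stock, brood_year, release_size
``cwt_recoveries``  group_id, region, season, year, gear, observed, lam
                    (one row per release group and sampled stratum,
                    zero-count rows included — zeros are informative)
``gsi_samples``     region, season, year, gear, n, <one column per focal
                    stock: summed assignment probabilities>, other
``run_sizes``       stock, year, estimate
``landings``        region, season, year, gear, estimate
``age_counts``      stock, season, year, age_<a> columns (optional table)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CWT, ReleaseGroup, make_total_groups
from .index import ModelIndex, RunConfig

RELEASE_COLS = ["group_id", "stock", "brood_year", "release_size"]
CWT_COLS = ["group_id", "region", "season", "year", "gear", "observed", "lam"]
GSI_BASE_COLS = ["region", "season", "year", "gear", "n"]
RUN_COLS = ["stock", "year", "estimate"]
LANDINGS_COLS = ["region", "season", "year", "gear", "estimate"]
AGE_BASE_COLS = ["stock", "season", "year"]


class ValidationError(ValueError):
    """Raised when an observation bundle violates its schema; the message
    lists every failure."""


@dataclass
class ObservationBundle:
    """All observation streams for one model fit."""

    releases: pd.DataFrame
    cwt_recoveries: pd.DataFrame
    gsi_samples: pd.DataFrame
    run_sizes: pd.DataFrame
    landings: pd.DataFrame
    age_counts: pd.DataFrame | None = None

    def release_groups(self) -> list[ReleaseGroup]:
        """CWT release groups from the release table plus one auto-generated
        total group per (stock, brood year)."""
        cwt = [
            ReleaseGroup(
                id=str(r.group_id),
                stock=str(r.stock),
                brood_year=int(r.brood_year),
                group_class=CWT,
                release_size=float(r.release_size),
            )
            for r in self.releases.itertuples(index=False)
        ]
        return cwt + make_total_groups(cwt)

    def gsi_strata(self) -> list[tuple]:
        return [
            (r.region, r.season, int(r.year), r.gear)
            for r in self.gsi_samples.itertuples(index=False)
        ]

    def validate(self, config: RunConfig) -> list[str]:
        """Return a list of human-readable schema violations (empty = valid)."""
        index = config.index
        errors: list[str] = []

        def check_cols(df, cols, name):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                errors.append(f"{name}: missing columns {missing}")
                return False
            return True

        def check_codes(df, name):
            for i, row in enumerate(df.itertuples(index=False)):
                if getattr(row, "region", None) is not None and row.region not in index.regions:
                    errors.append(f"{name} row {i}: unknown region {row.region!r}")
                if getattr(row, "season", None) is not None and row.season not in index.seasons:
                    errors.append(f"{name} row {i}: unknown season {row.season!r}")
                if getattr(row, "gear", None) is not None and row.gear not in index.gears:
                    errors.append(f"{name} row {i}: unknown gear {row.gear!r}")
                if getattr(row, "stock", None) is not None and row.stock not in index.stocks:
                    errors.append(f"{name} row {i}: unknown stock {row.stock!r}")

        if check_cols(self.releases, RELEASE_COLS, "releases"):
            check_codes(self.releases, "releases")
            if self.releases.group_id.duplicated().any():
                errors.append("releases: duplicated group_id")
            if (self.releases.release_size <= 0).any():
                errors.append("releases: release_size must be > 0")

        if check_cols(self.cwt_recoveries, CWT_COLS, "cwt_recoveries"):
            check_codes(self.cwt_recoveries, "cwt_recoveries")
            df = self.cwt_recoveries
            known = set(self.releases.group_id.astype(str))
            bad = set(df.group_id.astype(str)) - known
            if bad:
                errors.append(f"cwt_recoveries: unknown group ids {sorted(bad)[:5]}")
            if (df.observed < 0).any():
                errors.append("cwt_recoveries: negative observed counts")
            if ((df.lam < 0) | (df.lam > 1)).any():
                errors.append("cwt_recoveries: sampling fractions outside [0, 1]")
            key = ["group_id", "region", "season", "year", "gear"]
            dup = df.duplicated(subset=key, keep=False)
            if dup.any():
                conflicting = df[dup].groupby(key)["observed"].nunique()
                if (conflicting > 1).any():
                    errors.append(
                        "cwt_recoveries: conflicting duplicate rows for "
                        f"{conflicting[conflicting > 1].index.tolist()[:3]}"
                    )

        gsi_cols = GSI_BASE_COLS + list(index.stocks) + ["other"]
        if check_cols(self.gsi_samples, gsi_cols, "gsi_samples"):
            check_codes(self.gsi_samples, "gsi_samples")
            for i, row in enumerate(self.gsi_samples.itertuples(index=False)):
                sums = sum(getattr(row, s) for s in index.stocks) + row.other
                if abs(sums - row.n) > 1e-6 * max(1.0, row.n):
                    errors.append(
                        f"gsi_samples row {i}: stock sums + other = {sums} "
                        f"does not partition n = {row.n}"
                    )
                if any(getattr(row, s) < 0 for s in index.stocks) or row.other < 0:
                    errors.append(f"gsi_samples row {i}: negative assignment mass")

        if check_cols(self.run_sizes, RUN_COLS, "run_sizes"):
            check_codes(self.run_sizes, "run_sizes")
            if (self.run_sizes.estimate <= 0).any():
                errors.append("run_sizes: estimates must be > 0")

        if check_cols(self.landings, LANDINGS_COLS, "landings"):
            check_codes(self.landings, "landings")
            if (self.landings.estimate <= 0).any():
                errors.append("landings: estimates must be > 0")

        if self.age_counts is not None and len(self.age_counts):
            if check_cols(self.age_counts, AGE_BASE_COLS, "age_counts"):
                check_codes(self.age_counts, "age_counts")
                age_cols = [c for c in self.age_counts.columns if c.startswith("age_")]
                if not age_cols:
                    errors.append("age_counts: no age_<a> columns")
                elif (self.age_counts[age_cols] < 0).any().any():
                    errors.append("age_counts: negative counts")
        return errors

    def require_valid(self, config: RunConfig) -> "ObservationBundle":
        errors = self.validate(config)
        if errors:
            raise ValidationError("invalid observation bundle:\n  " + "\n  ".join(errors))
        return self

    def equals(self, other: "ObservationBundle") -> bool:
        for name in ("releases", "cwt_recoveries", "gsi_samples", "run_sizes", "landings"):
            a, b = getattr(self, name), getattr(other, name)
            if not a.reset_index(drop=True).equals(b.reset_index(drop=True)):
                return False
        a, b = self.age_counts, other.age_counts
        if (a is None) != (b is None):
            return bool((a is None or not len(a)) and (b is None or not len(b)))
        if a is not None and b is not None:
            return a.reset_index(drop=True).equals(b.reset_index(drop=True))
        return True
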