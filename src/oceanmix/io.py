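"""CSV/YAML reading and writing for observation bundles and parameter sets.

All on-disk artifacts are plain text: one CSV per observation table plus a
YAML truth/parameter file.  Writing then re-reading a bundle is lossless,
and re-writing a freshly read bundle reproduces the original bytes.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import ParameterSet
from .data import (
    AGE_BASE_COLS,
    CWT_COLS,
    GSI_BASE_COLS,
    LANDINGS_COLS,
    RELEASE_COLS,
    RUN_COLS,
    ObservationBundle,
    ValidationError,
)
from .index import ModelIndex, RunConfig

TABLES = {
    "releases": "releases.csv",
    "cwt_recoveries": "cwt_recoveries.csv",
    "gsi_samples": "gsi_samples.csv",
    "run_sizes": "run_sizes.csv",
    "landings": "landings.csv",
    "age_counts": "age_counts.csv",
}
TRUTH_FILE = "truth.yaml"


def write_bundle(bundle: ObservationBundle, directory, truth: ParameterSet | None = None,
                 config: RunConfig | None = None) -> list[Path]:
    """Write every table of a bundle (and optionally the generating truth)
    as CSV/YAML files under ``directory``; returns the written paths."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {directory}: {exc}") from exc
    written = []
    for attr, fname in TABLES.items():
        df = getattr(bundle, attr)
        if df is None:
            continue
        path = directory / fname
        df.to_csv(path, index=False)
        written.append(path)
    if truth is not None:
        path = directory / TRUTH_FILE
        with open(path, "w") as fh:
            yaml.safe_dump(params_to_dict(truth), fh, sort_keys=True)
        written.append(path)
    if config is not None:
        from .index import save_config

        path = directory / "config.yaml"
        save_config(config, path)
        written.append(path)
    return written


def read_observations(directory, config: RunConfig) -> ObservationBundle:
    """Read and validate an observation bundle from ``directory``.

    Raises :class:`ValidationError` listing every schema violation, or
    ``FileNotFoundError`` naming the first missing required table.
    """
    directory = Path(directory)
    frames = {}
    for attr, fname in TABLES.items():
        path = directory / fname
        if not path.exists():
            if attr == "age_counts":
                frames[attr] = None
                continue
            raise FileNotFoundError(f"missing required table {path}")
        # round_trip parsing keeps write -> read lossless at full precision
        frames[attr] = pd.read_csv(path, float_precision="round_trip")
    bundle = ObservationBundle(**frames)
    bundle.require_valid(config)
    # de-duplicate identical repeated CWT rows (conflicts already rejected)
    key = ["group_id", "region", "season", "year", "gear"]
    if bundle.cwt_recoveries.duplicated(subset=key).any():
        bundle.cwt_recoveries = bundle.cwt_recoveries.drop_duplicates(
            subset=key, keep="first"
        ).reset_index(drop=True)
    return bundle


def read_truth(directory) -> ParameterSet:
    with open(Path(directory) / TRUTH_FILE) as fh:
        return params_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# ParameterSet <-> plain dict
# ---------------------------------------------------------------------------

_ARRAY_FIELDS = ("pi", "f", "m", "M", "lam", "v", "tau", "p2bar")
_SCALAR_FIELDS = ("phi", "sigma_p2", "sigma_run", "cv_land", "sigma_delta")


def params_to_dict(params: ParameterSet) -> dict:
    """Serialize every ParameterSet field into YAML-safe plain types.

    Tuple-keyed mappings (``delta``, ``p2``) are flattened with ``|`` joined
    string keys.
    """
    out: dict = {}
    for name in _ARRAY_FIELDS:
        val = getattr(params, name)
        out[name] = None if val is None else np.asarray(val).tolist()
    for name in _SCALAR_FIELDS:
        out[name] = float(getattr(params, name))
    out["M0"] = {str(k): float(v) for k, v in params.M0.items()}
    out["U"] = {str(k): float(v) for k, v in params.U.items()}
    out["delta"] = {f"{k[0]}|{k[1]}": float(v) for k, v in params.delta.items()}
    out["p2"] = {
        "|".join(str(part) for part in k): float(v) for k, v in params.p2.items()
    }
    return out


def params_from_dict(d: dict) -> ParameterSet:
    def arr(name):
        v = d.get(name)
        return None if v is None else np.asarray(v, float)

    delta = {}
    for key, v in d.get("delta", {}).items():
        stock, brood = key.split("|")
        delta[(stock, int(brood))] = float(v)
    p2 = {}
    for key, v in d.get("p2", {}).items():
        region, season, year, gear = key.split("|")
        p2[(region, season, int(year), gear)] = float(v)
    return ParameterSet(
        pi=arr("pi"), f=arr("f"), m=arr("m"), M=arr("M"), lam=arr("lam"),
        v=arr("v"),
        M0={k: float(v) for k, v in d.get("M0", {}).items()},
        delta=delta,
        U={k: float(v) for k, v in d.get("U", {}).items()},
        tau=arr("tau"),
        phi=float(d.get("phi", 20.0)),
        p2bar=arr("p2bar"),
        sigma_p2=float(d.get("sigma_p2", 0.5)),
        p2=p2,
        sigma_run=float(d.get("sigma_run", 0.3)),
        cv_land=float(d.get("cv_land", 0.15)),
        sigma_delta=float(d.get("sigma_delta", 0.5)),
    )
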