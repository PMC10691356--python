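"""Posterior assembly: parameter packing, transforms, priors, and a batched
log-posterior kernel.

The sampler works on an unconstrained vector ``x`` of dimension ``d``:
simplex rows (the spatial distributions ``pi``) via a stick-breaking
transform, positive rates on the log scale, probabilities on the logit
scale.  :class:`ParameterSpec` owns the block layout, the transforms and
their Jacobians, prior densities, and prior sampling (used both for
initialization and for simulation-based calibration).

:class:`PosteriorKernel` evaluates the joint log-posterior for a whole
batch of parameter vectors at once — the cohort forward pass and every
likelihood component are vectorized over the batch — so that
finite-difference gradients (one batched evaluation of ``2 d`` displaced
points) are cheap enough for Hamiltonian Monte Carlo.  The batched kernel
is cross-checked against the row-by-row reference accumulation in
:func:`oceanmix.likelihoods.total_loglik`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, expit, logit as _slogit

from .cohort import CWT, TOTAL, ParameterSet, ReleaseGroup
from .data import ObservationBundle
from .index import ModelIndex, RunConfig
from .likelihoods import COMPONENTS, VARIANTS, MEAN_FLOOR

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


def _softplus(x):
    return np.logaddexp(0.0, x)


# ---------------------------------------------------------------------------
# Parameter layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    name: str
    shape: tuple[int, ...]
    offset: int

    @property
    def size(self) -> int:
        return int(np.prod(self.shape)) if self.shape else 1

    def view(self, X: np.ndarray) -> np.ndarray:
        """Slice this block out of a batch ``X`` of shape (B, d)."""
        flat = X[:, self.offset:self.offset + self.size]
        return flat.reshape(X.shape[0], *self.shape) if self.shape else flat[:, 0]


class ParameterSpec:
    """Block layout of the unconstrained parameter vector for one model fit.

    Every block is always present regardless of variant — components that a
    variant toggles off simply leave their parameters at the prior.
    """

    def __init__(self, config: RunConfig, cwt_groups: Sequence[ReleaseGroup],
                 total_groups: Sequence[ReleaseGroup], gsi_strata: Sequence[tuple],
                 p2_centered: bool = True):
        #: latent focal-proportion parameterization: centered (the latent is
        #: logit p2 itself, best when per-stratum samples are informative) or
        #: non-centered (standard-normal z, best when the latents are
        #: prior-only, e.g. in the CWT-only variant)
        self.p2_centered = bool(p2_centered)
        index = config.index
        self.config = config
        self.index = index
        self.cwt_groups = list(cwt_groups)
        self.total_groups = list(total_groups)
        self.gsi_strata = list(gsi_strata)
        opts = config.model_options
        self.f_by_year = bool(opts.get("f_by_year", True))
        self.estimate_delta = bool(opts.get("estimate_delta", False))
        self.estimate_v = bool(opts.get("estimate_v", False))
        self.delta_cells = sorted({(g.stock, g.brood_year) for g in cwt_groups})

        R, S, L = index.n_stocks, index.n_seasons, index.n_regions
        C, G, A = index.n_years, index.n_gears, index.n_ages

        blocks: list[Block] = []
        off = 0

        def add(name, shape):
            nonlocal off
            b = Block(name, shape, off)
            blocks.append(b)
            off += b.size
            return b

        add("pi_raw", (R, S, L - 1))
        add("log_M0", (len(cwt_groups),))
        if self.estimate_delta:
            add("delta", (len(self.delta_cells),))
        add("log_U", (len(total_groups),))
        add("log_f", (L, S, C, G) if self.f_by_year else (L, S, G))
        if self.estimate_v and A > 1:
            add("logit_v", (A - 1, G))
        if A > 1:
            add("logit_m", (R, A - 1))
        add("log_tau", (G,))
        add("log_phi", ())
        add("p2bar", (L, G))
        add("log_sigma_p2", ())
        # latent focal proportions; meaning depends on p2_centered
        add("p2_raw", (len(gsi_strata),))

        self.blocks = {b.name: b for b in blocks}
        self.dim = off
        self._priors = config.priors

    # -- transforms --------------------------------------------------------

    def unpack(self, X: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Constrained parameter arrays and the total log-prior (including
        transform Jacobians) for a batch ``X`` of shape (B, d)."""
        X = np.atleast_2d(X)
        B = X.shape[0]
        index = self.index
        pr = self._priors
        out: dict[str, np.ndarray] = {}
        lp = np.zeros(B)
        # extreme proposals (overflowing exp, vanishing sigma) legitimately
        # produce non-finite density, mapped to -inf by the kernel
        _err = np.errstate(all="ignore")
        _err.__enter__()

        # pi: stick-breaking + Dirichlet prior
        raw = self.blocks["pi_raw"].view(X)
        pi, logdet = _stick_forward(raw)
        out["pi"] = pi
        lp += logdet
        alpha = float(pr["pi"].get("alpha", 1.0))
        K = pi.shape[-1]
        n_rows = pi.shape[1] * pi.shape[2]
        lp += n_rows * float(gammaln(K * alpha) - K * gammaln(alpha))
        if alpha != 1.0:
            lp += (alpha - 1.0) * np.log(np.maximum(pi, 1e-300)).sum(axis=(1, 2, 3))

        def add_normal(name, key):
            b = self.blocks[name].view(X)
            mu, sig = float(pr[key]["mu"]), float(pr[key]["sigma"])
            dens = -0.5 * _LOG2PI - np.log(sig) - 0.5 * ((b - mu) / sig) ** 2
            if dens.ndim > 1:
                dens = dens.reshape(B, -1).sum(axis=1)
            return b, dens

        log_M0, dens = add_normal("log_M0", "log_M0")
        out["M0"] = np.exp(log_M0)
        lp += dens

        if "delta" in self.blocks:
            delta, dens = add_normal("delta", "delta")
            out["delta"] = delta
            lp += dens
        else:
            out["delta"] = np.zeros((B, len(self.delta_cells)))

        log_U, dens = add_normal("log_U", "log_U")
        out["U"] = np.exp(log_U)
        lp += dens

        log_f, dens = add_normal("log_f", "log_f")
        out["f"] = np.exp(log_f)
        lp += dens

        if "logit_v" in self.blocks:
            lv, dens = add_normal("logit_v", "logit_v")
            v = np.concatenate(
                [expit(lv), np.ones((B, 1, self.index.n_gears))], axis=1
            )
            out["v"] = v
            lp += dens
        else:
            out["v"] = np.ones((B, index.n_ages, index.n_gears))

        if "logit_m" in self.blocks:
            lm, dens = add_normal("logit_m", "logit_m")
            out["m"] = np.concatenate(
                [expit(lm), np.ones((B, index.n_stocks, 1))], axis=2
            )
            lp += dens
        else:
            out["m"] = np.ones((B, index.n_stocks, index.n_ages))

        # tau, phi: gamma priors on the natural scale + log-transform Jacobian
        for name, key in (("log_tau", "tau"), ("log_phi", "phi")):
            b = self.blocks[name].view(X)
            a = float(pr[key]["shape"])
            rate = float(pr[key]["rate"])
            dens = a * np.log(rate) - gammaln(a) + a * b - rate * np.exp(b)
            if b.ndim > 1:
                dens = dens.reshape(B, -1).sum(axis=1)
            out[key] = np.exp(b)
            lp += dens

        p2bar, dens = add_normal("p2bar", "p2bar")
        out["p2bar"] = p2bar
        lp += dens

        ls = self.blocks["log_sigma_p2"].view(X)
        s_scale = float(pr["sigma_p2"]["sigma"])
        sigma_p2 = np.exp(ls)
        lp += (np.log(2.0) - 0.5 * _LOG2PI - np.log(s_scale)
               - sigma_p2 ** 2 / (2.0 * s_scale ** 2) + ls)
        out["sigma_p2"] = sigma_p2

        # latent focal proportions under the logit-normal hierarchy
        # logit p2 ~ N(p2bar[region, gear], sigma_p2), in either the
        # centered or the non-centered parameterization
        raw = self.blocks["p2_raw"].view(X)
        if len(self.gsi_strata):
            li = np.array([self.index.region_i(k[0]) for k in self.gsi_strata])
            gi = np.array([self.index.gear_i(k[3]) for k in self.gsi_strata])
            means = p2bar[:, li, gi]
            sig = sigma_p2[:, None]
            if self.p2_centered:
                xp2 = raw
                lp += np.sum(
                    -0.5 * _LOG2PI - np.log(sig)
                    - 0.5 * ((xp2 - means) / sig) ** 2, axis=1,
                )
            else:
                lp += np.sum(-0.5 * _LOG2PI - 0.5 * raw * raw, axis=1)
                xp2 = means + sig * raw
        else:
            xp2 = raw
        out["logit_p2"] = xp2
        out["p2"] = expit(xp2)
        _err.__exit__(None, None, None)
        return out, lp

    def log_prior(self, X: np.ndarray) -> np.ndarray:
        return self.unpack(X)[1]

    # -- packing / conversion ----------------------------------------------

    def pack(self, params: ParameterSet) -> np.ndarray:
        """Unconstrained vector for a (fully specified) ParameterSet."""
        index = self.index
        x = np.zeros(self.dim)

        def put(name, values):
            b = self.blocks[name]
            x[b.offset:b.offset + b.size] = np.asarray(values, float).ravel()

        put("pi_raw", _stick_inverse(params.pi[None])[0])
        put("log_M0", np.log([params.M0[g.id] for g in self.cwt_groups]))
        if "delta" in self.blocks:
            put("delta", [params.delta.get(c, 0.0) for c in self.delta_cells])
        put("log_U", np.log([max(params.U[g.id], 1e-12) for g in self.total_groups]))
        f = params.f
        if not self.f_by_year and f.ndim == 4:
            f = f[:, :, 0, :]
        put("log_f", np.log(np.maximum(f, 1e-12)))
        if "logit_v" in self.blocks:
            v = params.vulnerability(index)
            put("logit_v", _slogit(np.clip(v[:-1], 1e-9, 1 - 1e-9)))
        if "logit_m" in self.blocks:
            put("logit_m", _slogit(np.clip(params.m[:, :-1], 1e-9, 1 - 1e-9)))
        tau = params.tau if params.tau is not None else np.full(index.n_gears, 20.0)
        put("log_tau", np.log(tau))
        put("log_phi", np.log(params.phi))
        p2bar = params.p2bar if params.p2bar is not None else np.zeros((index.n_regions, index.n_gears))
        put("p2bar", p2bar)
        put("log_sigma_p2", np.log(params.sigma_p2))
        if self.gsi_strata:
            lx = _slogit(np.clip(
                [params.p2_for(index, k) for k in self.gsi_strata], 1e-9, 1 - 1e-9
            ))
            if self.p2_centered:
                put("p2_raw", lx)
            else:
                means = np.array([
                    p2bar[index.region_i(k[0]), index.gear_i(k[3])]
                    for k in self.gsi_strata
                ])
                put("p2_raw", (lx - means) / params.sigma_p2)
        return x

    def to_parameter_set(self, x: np.ndarray, lam: np.ndarray | None = None) -> ParameterSet:
        """ParameterSet for a single unconstrained vector."""
        index = self.index
        p, _ = self.unpack(x[None])
        f = p["f"][0]
        if not self.f_by_year:
            f = np.repeat(f[:, :, None, :], index.n_years, axis=2)
        if lam is None:
            lam = np.zeros_like(f)
        return ParameterSet(
            pi=p["pi"][0], f=f, m=p["m"][0],
            M=self.config.natural_mortality, lam=lam,
            v=p["v"][0] if self.estimate_v else None,
            M0={g.id: float(p["M0"][0, j]) for j, g in enumerate(self.cwt_groups)},
            delta={c: float(p["delta"][0, j]) for j, c in enumerate(self.delta_cells)
                   if self.estimate_delta},
            U={g.id: float(p["U"][0, j]) for j, g in enumerate(self.total_groups)},
            tau=p["tau"][0], phi=float(p["phi"][0]),
            p2bar=p["p2bar"][0], sigma_p2=float(p["sigma_p2"][0]),
            p2={k: float(p["p2"][0, i]) for i, k in enumerate(self.gsi_strata)},
            sigma_run=self.config.fixed_constants["sigma_run"],
            cv_land=self.config.fixed_constants["cv_land"],
            sigma_delta=self.config.fixed_constants["sigma_delta"],
        )

    # -- prior sampling -----------------------------------------------------

    def sample_prior(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw unconstrained vectors from the prior (hierarchically for the
        latent focal proportions).  Shape (size, d)."""
        pr = self._priors
        X = np.zeros((size, self.dim))

        def put(name, values):
            b = self.blocks[name]
            X[:, b.offset:b.offset + b.size] = values.reshape(size, -1)

        alpha = float(pr["pi"].get("alpha", 1.0))
        b = self.blocks["pi_raw"]
        R, S, Km1 = b.shape
        w = rng.dirichlet(np.full(Km1 + 1, alpha), size=(size, R, S))
        put("pi_raw", _stick_inverse(w))

        for name, key in (("log_M0", "log_M0"), ("delta", "delta"),
                          ("log_U", "log_U"), ("log_f", "log_f"),
                          ("logit_v", "logit_v"), ("logit_m", "logit_m"),
                          ("p2bar", "p2bar")):
            if name not in self.blocks:
                continue
            blk = self.blocks[name]
            put(name, rng.normal(pr[key]["mu"], pr[key]["sigma"], size=(size, blk.size)))

        for name, key in (("log_tau", "tau"), ("log_phi", "phi")):
            blk = self.blocks[name]
            draws = rng.gamma(pr[key]["shape"], 1.0 / pr[key]["rate"],
                              size=(size, blk.size))
            put(name, np.log(draws))

        sigma = np.abs(rng.normal(0.0, pr["sigma_p2"]["sigma"], size=(size, 1)))
        put("log_sigma_p2", np.log(np.maximum(sigma, 1e-12)))

        if len(self.gsi_strata):
            z = rng.standard_normal((size, len(self.gsi_strata)))
            if self.p2_centered:
                bbar = self.blocks["p2bar"]
                p2bar = X[:, bbar.offset:bbar.offset + bbar.size].reshape(
                    size, self.index.n_regions, self.index.n_gears
                )
                li = np.array([self.index.region_i(k[0]) for k in self.gsi_strata])
                gi = np.array([self.index.gear_i(k[3]) for k in self.gsi_strata])
                put("p2_raw", p2bar[:, li, gi] + sigma * z)
            else:
                put("p2_raw", z)
        return X

    def init_point(self, rng: np.random.Generator, jitter: float = 0.2) -> np.ndarray:
        """Prior-median initialization with Gaussian jitter."""
        from scipy.stats import gamma as _gamma

        pr = self._priors
        x = np.zeros(self.dim)

        def put(name, val):
            b = self.blocks[name]
            x[b.offset:b.offset + b.size] = val

        for name, key in (("log_M0", "log_M0"), ("delta", "delta"),
                          ("log_U", "log_U"), ("log_f", "log_f"),
                          ("logit_v", "logit_v"), ("logit_m", "logit_m"),
                          ("p2bar", "p2bar")):
            if name in self.blocks:
                put(name, pr[key]["mu"])
        for name, key in (("log_tau", "tau"), ("log_phi", "phi")):
            med = _gamma.ppf(0.5, pr[key]["shape"], scale=1.0 / pr[key]["rate"])
            put(name, np.log(med))
        put("log_sigma_p2", np.log(pr["sigma_p2"]["sigma"] * 0.674))
        put("p2_raw", pr["p2bar"]["mu"] if self.p2_centered else 0.0)
        return x + jitter * rng.standard_normal(self.dim)

    # -- constrained naming --------------------------------------------------

    def constrained_names(self) -> list[str]:
        index = self.index
        names: list[str] = []
        for stock in index.stocks:
            for season in index.seasons:
                for region in index.regions:
                    names.append(f"pi[{stock},{season},{region}]")
        names += [f"M0[{g.id}]" for g in self.cwt_groups]
        if self.estimate_delta:
            names += [f"delta[{s},{b}]" for s, b in self.delta_cells]
        names += [f"U[{g.id}]" for g in self.total_groups]
        fshape = self.blocks["log_f"].shape
        if self.f_by_year:
            names += [
                f"f[{r},{s},{y},{g}]"
                for r in index.regions for s in index.seasons
                for y in index.year_list for g in index.gears
            ]
        else:
            names += [
                f"f[{r},{s},{g}]"
                for r in index.regions for s in index.seasons for g in index.gears
            ]
        if self.estimate_v:
            names += [
                f"v[{a},{g}]" for a in index.age_list[:-1] for g in index.gears
            ]
        if index.n_ages > 1:
            names += [
                f"m[{s},{a}]" for s in index.stocks for a in index.age_list[:-1]
            ]
        names += [f"tau[{g}]" for g in index.gears]
        names += ["phi"]
        names += [f"p2bar[{r},{g}]" for r in index.regions for g in index.gears]
        names += ["sigma_p2"]
        names += ["p2[" + ",".join(str(p) for p in k) + "]" for k in self.gsi_strata]
        return names

    def constrain(self, X: np.ndarray) -> np.ndarray:
        """Constrained parameter matrix (B, P) matching constrained_names."""
        p, _ = self.unpack(X)
        B = np.atleast_2d(X).shape[0]
        cols = [p["pi"].reshape(B, -1), p["M0"]]
        if self.estimate_delta:
            cols.append(p["delta"])
        cols.append(p["U"])
        cols.append(p["f"].reshape(B, -1))
        if self.estimate_v:
            cols.append(p["v"][:, :-1, :].reshape(B, -1))
        if self.index.n_ages > 1:
            cols.append(p["m"][:, :, :-1].reshape(B, -1))
        cols += [p["tau"], p["phi"].reshape(B, 1), p["p2bar"].reshape(B, -1),
                 p["sigma_p2"].reshape(B, 1)]
        if len(self.gsi_strata):
            cols.append(p["p2"])
        else:
            cols.append(np.zeros((B, 0)))
        return np.concatenate(cols, axis=1)


# ---------------------------------------------------------------------------
# Stick-breaking transform
# ---------------------------------------------------------------------------

def _stick_forward(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched stick-breaking: Y (B, R, S, K-1) -> simplex (B, R, S, K) and
    summed log|Jacobian| per batch element."""
    B = Y.shape[0]
    K = Y.shape[-1] + 1
    W = np.zeros(Y.shape[:-1] + (K,))
    rem = np.ones(Y.shape[:-1])
    logdet = np.zeros(B)
    for k in range(K - 1):
        zk = expit(Y[..., k] - np.log(K - 1 - k))
        W[..., k] = rem * zk
        term = (np.log(np.maximum(zk, 1e-300))
                + np.log(np.maximum(1.0 - zk, 1e-300))
                + np.log(np.maximum(rem, 1e-300)))
        logdet += term.reshape(B, -1).sum(axis=1)
        rem = rem * (1.0 - zk)
    W[..., K - 1] = rem
    return W, logdet


def _stick_inverse(W: np.ndarray) -> np.ndarray:
    """Inverse stick-breaking: simplex (..., K) -> unconstrained (..., K-1)."""
    W = np.asarray(W, float)
    K = W.shape[-1]
    Y = np.zeros(W.shape[:-1] + (K - 1,))
    rem = np.ones(W.shape[:-1])
    for k in range(K - 1):
        z = np.clip(W[..., k] / np.maximum(rem, 1e-300), 1e-12, 1 - 1e-12)
        Y[..., k] = _slogit(z) + np.log(K - 1 - k)
        rem = rem - W[..., k]
    return Y


# ---------------------------------------------------------------------------
# Batched posterior kernel
# ---------------------------------------------------------------------------

class PosteriorKernel:
    """Batched evaluation of the joint log-posterior for one dataset.

    Parameters
    ----------
    config, data : run configuration and validated observation bundle.
    components : variant name (see :data:`oceanmix.likelihoods.VARIANTS`)
        or an explicit set of component names.  The latent-proportion
        hierarchy is part of the prior and always active.
    """

    def __init__(self, config: RunConfig, data: ObservationBundle,
                 components: Iterable[str] | str = "cwt_gsi",
                 engine: str = "auto"):
        if isinstance(components, str):
            components = VARIANTS[components]
        self.components = frozenset(components)
        unknown = self.components - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components {sorted(unknown)}")
        self.config = config
        self.data = data
        index = config.index
        self.index = index

        from ._fastkernel import NUMBA_AVAILABLE

        if engine == "auto":
            engine = "numba" if NUMBA_AVAILABLE else "numpy"
        if engine not in ("numba", "numpy"):
            raise ValueError(f"unknown engine {engine!r}")
        if engine == "numba" and not NUMBA_AVAILABLE:
            logger.warning("numba unavailable; falling back to the numpy path")
            engine = "numpy"
        self.engine = engine

        groups = data.release_groups()
        self.cwt_groups = [g for g in groups if g.group_class == CWT]
        self.total_groups = [g for g in groups if g.group_class == TOTAL]
        # centered latent proportions when GSI data inform them, the
        # non-centered form when they would sit at the hierarchical prior
        centered = bool(self.components & {"gsi", "p2"})
        self.spec = ParameterSpec(
            config, self.cwt_groups, self.total_groups, data.gsi_strata(),
            p2_centered=centered,
        )
        self._precompute()
        self._precompute_flat()

    # -- static structure ----------------------------------------------------

    def _precompute(self) -> None:
        index = self.index
        y0 = index.years[0]
        a0 = index.ages[0]
        self.T = 4 * (index.terminal_age - 2) + 3
        self.s_of_t = np.array([t % 4 for t in range(self.T)])
        self.a_of_t = np.array([a0 + t // 4 for t in range(self.T)])

        groups = self.cwt_groups + self.total_groups
        self.J = len(groups)
        self.Jc = len(self.cwt_groups)
        self.r_of_j = np.array([index.stock_i(g.stock) for g in groups])
        self.brood_of_j = np.array([g.brood_year for g in groups])
        for g in groups:
            if g.brood_year + a0 < y0:
                raise ValueError(
                    f"group {g.id} enters the ocean before the year range"
                )
        # calendar-year index per (j, t); invalid steps masked
        self.c_of_jt = self.brood_of_j[:, None] + self.a_of_t[None, :] - y0
        self.valid_jt = (self.c_of_jt >= 0) & (self.c_of_jt < index.n_years)
        self.c_clip = np.clip(self.c_of_jt, 0, index.n_years - 1)

        self.R_release = np.array([g.release_size for g in self.cwt_groups])
        cell_of = {c: i for i, c in enumerate(self.spec.delta_cells)}
        self.delta_idx = np.array(
            [cell_of[(g.stock, g.brood_year)] for g in self.cwt_groups], int
        )
        # link matrix: total group <- its CWT groups
        self.link = np.zeros((len(self.total_groups), self.Jc))
        cwt_pos = {g.id: j for j, g in enumerate(self.cwt_groups)}
        for i, g in enumerate(self.total_groups):
            for cid in g.linked_cwt_ids:
                self.link[i, cwt_pos[cid]] = 1.0

        # CWT observation rows, grouped by step
        offs = {s: i for i, s in enumerate(index.seasons)}
        rows_by_t: dict[int, list] = {}
        self.cwt_y, self.cwt_g = [], []
        skipped = 0
        for i, row in enumerate(self.data.cwt_recoveries.itertuples(index=False)):
            j = cwt_pos[str(row.group_id)]
            age = int(row.year) - self.brood_of_j[j]
            t = 4 * (age - a0) + offs[row.season]
            if not (0 <= t < self.T) or not self.valid_jt[j, t]:
                skipped += 1
                continue
            rows_by_t.setdefault(t, []).append(
                (len(self.cwt_y), j, index.region_i(row.region),
                 index.gear_i(row.gear), float(row.lam))
            )
            self.cwt_y.append(float(row.observed))
            self.cwt_g.append(index.gear_i(row.gear))
        if skipped:
            logger.warning("%d CWT rows outside the cohort schedule ignored", skipped)
        self.cwt_y = np.array(self.cwt_y)
        self.cwt_g = np.array(self.cwt_g, int)
        self.cwt_rows_by_t = {
            t: tuple(np.array(v) for v in zip(*rows))
            for t, rows in rows_by_t.items()
        }
        # constant part of the NB loglik and unique-count tables per gear
        self.nb_const = -float(gammaln(self.cwt_y + 1.0).sum()) if len(self.cwt_y) else 0.0
        self.nb_tables = []
        for g in range(index.n_gears):
            ys = self.cwt_y[self.cwt_g == g]
            uy, cnt = np.unique(ys, return_counts=True)
            self.nb_tables.append((uy, cnt.astype(float)))

        # strata needed for expected stock catch (GSI union landings)
        strata: list[tuple] = []
        seen = {}
        for k in self.spec.gsi_strata:
            seen[k] = len(strata)
            strata.append(k)
        land_rows = list(self.data.landings.itertuples(index=False))
        for row in land_rows:
            k = (row.region, row.season, int(row.year), row.gear)
            if k not in seen:
                seen[k] = len(strata)
                strata.append(k)
        self.strata = strata
        self.K_strata = len(strata)

        trip_by_t: dict[int, list] = {}
        for k, (region, season, year, gear) in enumerate(strata):
            l, s, g = index.region_i(region), offs[season], index.gear_i(gear)
            for jt, grp in enumerate(self.total_groups):
                j = self.Jc + jt
                age = year - grp.brood_year
                if not (a0 <= age <= index.terminal_age):
                    continue
                t = 4 * (age - a0) + s
                if t >= self.T or not self.valid_jt[j, t]:
                    continue
                trip_by_t.setdefault(t, []).append((k, j, l, g, self.r_of_j[j]))
        self.mu_trip_by_t = {
            t: tuple(np.array(v) for v in zip(*rows))
            for t, rows in trip_by_t.items()
        }

        # run-size accumulation (fall steps of total groups)
        self.run_acc_by_t = {}
        for t in range(self.T):
            if index.seasons[self.s_of_t[t]] != "fall":
                continue
            js, rs, cs = [], [], []
            for jt in range(len(self.total_groups)):
                j = self.Jc + jt
                if self.valid_jt[j, t]:
                    js.append(j)
                    rs.append(self.r_of_j[j])
                    cs.append(self.c_of_jt[j, t])
            if js:
                self.run_acc_by_t[t] = (np.array(js), np.array(rs), np.array(cs))

        # GSI rows
        gsi = self.data.gsi_samples
        self.n_gsi = len(gsi)
        if self.n_gsi:
            self.gsi_k = np.array([seen[k] for k in self.spec.gsi_strata], int)
            sums = gsi[list(index.stocks)].to_numpy(float)
            other = gsi["other"].to_numpy(float)
            self.gsi_n = gsi["n"].to_numpy(float)
            y = np.concatenate([sums, other[:, None]], axis=1) / self.gsi_n[:, None]
            y[np.abs(y) < 1e-15] = 0.0
            y /= y.sum(axis=1, keepdims=True)
            self.gsi_y = y                                  # (n_gsi, K)
            self.gsi_zero = y == 0.0
            self.gsi_pos = ~self.gsi_zero
            self.gsi_multi = self.gsi_pos.sum(axis=1) > 1
            logx = np.zeros_like(y)
            logx[self.gsi_pos] = np.log(y[self.gsi_pos])
            self.gsi_logx = logx
            self.p2_k = np.round(sums.sum(axis=1))
            self.p2_n = np.round(self.gsi_n)
            self.p2_const = float(
                (gammaln(self.p2_n + 1) - gammaln(self.p2_k + 1)
                 - gammaln(self.p2_n - self.p2_k + 1)).sum()
            )

        # landings rows
        self.n_land = len(land_rows)
        if self.n_land:
            self.land_k = np.array(
                [seen[(r.region, r.season, int(r.year), r.gear)] for r in land_rows], int
            )
            self.land_obs = np.array([float(r.estimate) for r in land_rows])
            gsi_pos_of = {k: i for i, k in enumerate(self.spec.gsi_strata)}
            self.land_latent = np.array(
                [gsi_pos_of.get((r.region, r.season, int(r.year), r.gear), -1)
                 for r in land_rows], int
            )
            self.land_l = np.array([index.region_i(r.region) for r in land_rows])
            self.land_g = np.array([index.gear_i(r.gear) for r in land_rows])

        # run-size rows
        runs = list(self.data.run_sizes.itertuples(index=False))
        self.n_run = len(runs)
        if self.n_run:
            self.run_r = np.array([index.stock_i(r.stock) for r in runs])
            self.run_c = np.array([index.year_i(int(r.year)) for r in runs])
            self.run_log_obs = np.log([float(r.estimate) for r in runs])

        # age rows
        self.age_rows = []
        if self.data.age_counts is not None and len(self.data.age_counts):
            age_cols = [c for c in self.data.age_counts.columns if c.startswith("age_")]
            self.age_gather_by_t: dict[int, list] = {}
            for i, row in enumerate(self.data.age_counts.itertuples(index=False)):
                r = index.stock_i(row.stock)
                s = offs[row.season]
                c = index.year_i(int(row.year))
                counts = np.array([float(getattr(row, col)) for col in age_cols])
                ages = np.array([int(col.split("_")[1]) for col in age_cols])
                self.age_rows.append(counts)
                for a_pos, age in enumerate(ages):
                    if not (a0 <= age <= index.terminal_age):
                        continue
                    t = 4 * (age - a0) + s
                    if t >= self.T:
                        continue
                    brood = int(row.year) - age
                    for jt, grp in enumerate(self.total_groups):
                        if grp.brood_year == brood and grp.stock == row.stock:
                            j = self.Jc + jt
                            if self.valid_jt[j, t]:
                                self.age_gather_by_t.setdefault(t, []).append(
                                    (i, a_pos, j)
                                )
            self.age_gather_by_t = {
                t: tuple(np.array(v) for v in zip(*rows))
                for t, rows in self.age_gather_by_t.items()
            }
            self.age_counts_mat = np.array(self.age_rows)  # (n_age_rows, A_cols)
            self.age_const = float(
                (gammaln(self.age_counts_mat.sum(axis=1) + 1)
                 - gammaln(self.age_counts_mat + 1).sum(axis=1)).sum()
            )

    def _precompute_flat(self) -> None:
        """Flattened, step-sorted index arrays consumed by the compiled
        (numba) likelihood core."""
        index = self.index
        T, G = self.T, index.n_gears

        def flatten_by_t(by_t: dict, n_fields: int):
            ptr = np.zeros(T + 1, np.int64)
            fields = [[] for _ in range(n_fields)]
            for t in range(T):
                if t in by_t:
                    cols = by_t[t]
                    for i in range(n_fields):
                        fields[i].extend(np.asarray(cols[i]).tolist())
                ptr[t + 1] = len(fields[0])
            return ptr, [np.array(f, np.int64) for f in fields]

        ptr, (row, j, l, g, lam_i) = flatten_by_t(
            {t: v[:5] for t, v in self.cwt_rows_by_t.items()}, 5
        )
        # lam is float; re-extract in order
        lam = np.zeros(len(row))
        pos = 0
        for t in range(T):
            if t in self.cwt_rows_by_t:
                lams = np.asarray(self.cwt_rows_by_t[t][4], float)
                lam[pos:pos + len(lams)] = lams
                pos += len(lams)
        self._flat_cwt = (ptr, row, j, l, g, lam)

        uy_vals, uy_cnt = [], []
        uy_ptr = np.zeros(G + 1, np.int64)
        for gi, (uy, cnt) in enumerate(self.nb_tables):
            uy_vals.extend(uy.tolist())
            uy_cnt.extend(cnt.tolist())
            uy_ptr[gi + 1] = len(uy_vals)
        self._flat_uy = (np.array(uy_vals), np.array(uy_cnt), uy_ptr)

        trip_ptr, (tk, tj, tl, tg, tr) = flatten_by_t(self.mu_trip_by_t, 5)
        self._flat_trip = (trip_ptr, tk, tj, tl, tg, tr)

        n_age = len(self.age_rows)
        if n_age:
            age_ptr, (ar, ac, aj) = flatten_by_t(self.age_gather_by_t, 3)
            self._flat_age = (age_ptr, ar, ac, aj,
                              np.asarray(self.age_counts_mat, float), self.age_const)
        else:
            z = np.zeros(0, np.int64)
            self._flat_age = (np.zeros(T + 1, np.int64), z, z, z,
                              np.zeros((0, 1)), 0.0)

        self._M_step = np.array(
            [self.config.natural_mortality[a - index.ages[0]] for a in self.a_of_t]
        )
        self._is_fall = np.array(
            [index.seasons[s] == "fall" for s in self.s_of_t]
        )
        K1 = index.n_stocks + 1
        if self.n_gsi:
            self._flat_gsi = (self.gsi_k, self.gsi_n, self.gsi_zero,
                              self.gsi_pos, self.gsi_multi, self.gsi_logx)
        else:
            self._flat_gsi = (np.zeros(0, np.int64), np.zeros(0),
                              np.zeros((0, K1), bool), np.zeros((0, K1), bool),
                              np.zeros(0, bool), np.zeros((0, K1)))
        if self.n_run:
            self._flat_run = (self.run_r.astype(np.int64),
                              self.run_c.astype(np.int64), self.run_log_obs)
        else:
            self._flat_run = (np.zeros(0, np.int64), np.zeros(0, np.int64),
                              np.zeros(0))
        if self.n_land:
            self._flat_land = (self.land_k.astype(np.int64), self.land_obs)
        else:
            self._flat_land = (np.zeros(0, np.int64), np.zeros(0))

    def _logp_fast(self, p: Mapping[str, np.ndarray]) -> np.ndarray:
        """Compiled likelihood of the toggled components (minus the cheap
        p2-binomial part, added by the caller)."""
        from ._fastkernel import logp_core

        index = self.index
        B = p["pi"].shape[0]
        f = p["f"]
        if not self.spec.f_by_year:
            f = f[:, :, :, None, :]
        dev = p["delta"][:, self.delta_idx] if p["delta"].shape[1] else np.zeros(
            (B, self.Jc)
        )
        if self.n_land:
            latent = self.land_latent
            plugin = expit(p["p2bar"][:, self.land_l, self.land_g])
            if p["p2"].shape[1]:
                p2_land = np.where(latent >= 0,
                                   p["p2"][:, np.maximum(latent, 0)], plugin)
            else:
                p2_land = plugin
        else:
            p2_land = np.zeros((B, 0))

        ptr, row, jj, ll_, gg, lam = self._flat_cwt
        uy_vals, uy_cnt, uy_ptr = self._flat_uy
        trip_ptr, tk, tj, tl, tg, tr = self._flat_trip
        age_ptr, ar, ac, aj, age_counts, age_const = self._flat_age
        gsi_k, gsi_n, gsi_zero, gsi_pos, gsi_multi, gsi_logx = self._flat_gsi
        run_r, run_c, run_logobs = self._flat_run
        land_k, land_obs = self._flat_land
        eq_seq = self.config.model_options.get("catch_equation") == "sequential"

        return logp_core(
            p["pi"], f, self.spec.f_by_year, p["v"], p["m"],
            p["M0"] + dev, p["U"], p["tau"], p["phi"], p["p2"], p2_land,
            self.r_of_j.astype(np.int64), self.c_clip.astype(np.int64),
            self.valid_jt, self.s_of_t.astype(np.int64),
            (self.a_of_t - index.ages[0]).astype(np.int64),
            self._M_step, self._is_fall, self.Jc,
            self.link, np.asarray(self.R_release, float),
            ptr, row, jj, ll_, gg, lam, np.asarray(self.cwt_y, float),
            self.cwt_g.astype(np.int64), uy_vals, uy_cnt, uy_ptr, self.nb_const,
            self.K_strata, trip_ptr, tk, tj, tl, tg, tr,
            gsi_k.astype(np.int64), gsi_n, gsi_zero, gsi_pos, gsi_multi, gsi_logx,
            run_r, run_c, run_logobs,
            float(self.config.fixed_constants["sigma_run"]),
            land_k, land_obs, float(self.config.fixed_constants["cv_land"]),
            age_ptr, ar, ac, aj, age_counts, age_const,
            "cwt" in self.components, "gsi" in self.components,
            "run_size" in self.components, "landings" in self.components,
            "age" in self.components and len(self.age_rows) > 0,
            eq_seq, MEAN_FLOOR, index.n_years,
        )

    def _p2_binom(self, p: Mapping[str, np.ndarray]) -> np.ndarray:
        xp2 = p["logit_p2"]
        return (self.p2_const
                + (-self.p2_k * _softplus(-xp2)
                   - (self.p2_n - self.p2_k) * _softplus(xp2)).sum(axis=1))

    # -- forward pass ---------------------------------------------------------

    def _forward(self, p: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Batched cohort dynamics; returns expected recoveries, stratum
        catches by stock, run sizes, and age-structure abundances."""
        index = self.index
        B = p["pi"].shape[0]
        eq = self.config.model_options.get("catch_equation", "baranov")
        M_by_age = self.config.natural_mortality

        # entry abundance
        m0 = p["M0"]
        dev = p["delta"][:, self.delta_idx] if p["delta"].shape[1] else 0.0
        cwt_entry = self.R_release[None, :] * np.exp(-(m0 + dev))
        total_entry = cwt_entry @ self.link.T + p["U"]
        N = np.concatenate([cwt_entry, total_entry], axis=1)  # (B, J)

        exp_rec = np.zeros((B, len(self.cwt_y)))
        mu = np.zeros((B, self.K_strata, index.n_stocks))
        run = np.zeros((B, index.n_stocks, index.n_years))
        n_age_rows = len(self.age_rows)
        n_age_cols = self.age_counts_mat.shape[1] if n_age_rows else 0
        age_N = np.zeros((B, n_age_rows, n_age_cols)) if n_age_rows else None

        f = p["f"]
        for t in range(self.T):
            s = int(self.s_of_t[t])
            a = int(self.a_of_t[t])
            a_i = a - index.ages[0]
            if age_N is not None and t in self.age_gather_by_t:
                ri, ai, ji = self.age_gather_by_t[t]
                age_N[:, ri, ai] = N[:, ji]

            pi_j = p["pi"][:, self.r_of_j, s, :]               # (B, J, L)
            if self.spec.f_by_year:
                f_s = f[:, :, s, :, :]                          # (B, L, C, G)
                f_step = f_s[:, :, self.c_clip[:, t], :]        # (B, L, J, G)
                f_step = np.swapaxes(f_step, 1, 2)              # (B, J, L, G)
            else:
                f_step = f[:, None, :, s, :]                    # (B, 1, L, G)
            v_t = p["v"][:, a_i, :]                             # (B, G)
            F = v_t[:, None, None, :] * f_step                  # (B, J|1, L, G)
            Fl = F.sum(axis=3)
            M = float(M_by_age[a_i])
            if eq == "baranov":
                Z = Fl + M
                ratio = -np.expm1(-Z) / Z
                alloc = N[:, :, None] * pi_j
                catch = alloc[..., None] * F * ratio[..., None]
                surv_l = alloc * np.exp(-Z)
            else:  # sequential
                alloc = N[:, :, None] * pi_j
                with np.errstate(invalid="ignore", divide="ignore"):
                    share = np.where(Fl[..., None] > 0,
                                     F / np.where(Fl[..., None] > 0, Fl[..., None], 1.0),
                                     0.0)
                catch = alloc[..., None] * (-np.expm1(-Fl))[..., None] * share
                surv_l = alloc * np.exp(-(Fl + M))
            survivors = surv_l.sum(axis=2)                      # (B, J)

            if t in self.cwt_rows_by_t:
                ridx, js, ls, gs, lams = self.cwt_rows_by_t[t]
                exp_rec[:, ridx] += lams[None, :] * catch[:, js, ls, gs]
            if t in self.mu_trip_by_t:
                ks, js, ls, gs, rs = self.mu_trip_by_t[t]
                mu[:, ks, rs] += catch[:, js, ls, gs]

            if index.seasons[s] == "fall":
                mat = survivors * p["m"][:, self.r_of_j, a_i]
                if t in self.run_acc_by_t:
                    js, rs, cs = self.run_acc_by_t[t]
                    run[:, rs, cs] += mat[:, js]
                N = survivors - mat
            else:
                N = survivors
        return {"exp_rec": exp_rec, "mu": mu, "run": run, "age_N": age_N}

    # -- likelihood components --------------------------------------------

    def component_logliks(self, p: Mapping[str, np.ndarray],
                          fwd: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        index = self.index
        B = p["pi"].shape[0]
        out: dict[str, np.ndarray] = {}

        if "cwt" in self.components and len(self.cwt_y):
            tau = p["tau"]                                       # (B, G)
            mu_r = np.maximum(fwd["exp_rec"], MEAN_FLOOR)
            tau_r = tau[:, self.cwt_g]                            # (B, n)
            ll = np.full(B, self.nb_const)
            for g, (uy, cnt) in enumerate(self.nb_tables):
                if not len(uy):
                    continue
                tg = tau[:, g:g + 1]
                ll += gammaln(tg + uy[None, :]) @ cnt
                ll -= cnt.sum() * gammaln(tg[:, 0])
            log_tm = np.log(tau_r + mu_r)
            ll += (tau_r * np.log(tau_r) - (tau_r + self.cwt_y[None, :]) * log_tm
                   + self.cwt_y[None, :] * np.log(mu_r)).sum(axis=1)
            out["cwt"] = ll

        if self.n_gsi and ("gsi" in self.components or "p2" in self.components):
            mu_g = fwd["mu"][:, self.gsi_k, :]                    # (B, n_gsi, R)
            muF = np.maximum(mu_g.sum(axis=2), 1e-300)
            p2 = p["p2"]                                          # (B, n_gsi)
            if "gsi" in self.components:
                comp = np.empty((B, self.n_gsi, index.n_stocks + 1))
                comp[:, :, :-1] = p2[..., None] * mu_g / muF[..., None]
                comp[:, :, -1] = 1.0 - p2
                comp = np.maximum(comp, 1e-10)
                comp /= comp.sum(axis=2, keepdims=True)
                out["gsi"] = self._zoid_batch(comp, p["phi"])
            if "p2" in self.components:
                xp2 = p["logit_p2"]
                ll = (self.p2_const
                      + (-self.p2_k * _softplus(-xp2)
                         - (self.p2_n - self.p2_k) * _softplus(xp2)).sum(axis=1))
                out["p2"] = ll

        if "run_size" in self.components and self.n_run:
            run_hat = np.maximum(fwd["run"][:, self.run_r, self.run_c], MEAN_FLOOR)
            sig = self.config.fixed_constants["sigma_run"]
            z = (self.run_log_obs[None, :] - np.log(run_hat)) / sig
            out["run_size"] = np.sum(
                -0.5 * _LOG2PI - np.log(sig) - 0.5 * z * z, axis=1
            )

        if "landings" in self.components and self.n_land:
            mu_land = fwd["mu"][:, self.land_k, :].sum(axis=2)     # (B, n_land)
            latent = self.land_latent
            p2_land = np.where(
                latent >= 0,
                p["p2"][:, np.maximum(latent, 0)] if p["p2"].shape[1] else 1.0,
                expit(p["p2bar"][:, self.land_l, self.land_g]),
            )
            mu_tot = np.maximum(mu_land / p2_land, MEAN_FLOOR)
            cv = self.config.fixed_constants["cv_land"]
            sd = cv * mu_tot
            z = (self.land_obs[None, :] - mu_tot) / sd
            out["landings"] = np.sum(
                -0.5 * _LOG2PI - np.log(sd) - 0.5 * z * z, axis=1
            )

        if "age" in self.components and fwd["age_N"] is not None:
            NN = fwd["age_N"]
            tot = np.maximum(NN.sum(axis=2, keepdims=True), 1e-300)
            logp3 = np.log(np.maximum(NN / tot, 1e-300))
            out["age"] = self.age_const + (self.age_counts_mat[None] * logp3).sum(
                axis=(1, 2)
            )
        return out

    def _zoid_batch(self, comp: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Zero-and-one-inflated Dirichlet log-density, batched over rows."""
        n = self.gsi_n[None, :, None]
        log1mp = np.log1p(-np.minimum(comp, 1.0 - 1e-12))
        log_theta0 = n * log1mp                              # (B, n_gsi, K)
        log_empty = log_theta0.sum(axis=2)
        # log(1 - exp(log_empty)): admissible patterns exclude the empty set
        log_norm = np.log(-np.expm1(np.minimum(log_empty, -1e-300)))
        pattern = (
            np.where(self.gsi_zero[None], log_theta0, 0.0).sum(axis=2)
            + np.where(self.gsi_pos[None],
                       np.log(-np.expm1(np.minimum(log_theta0, -1e-300))),
                       0.0).sum(axis=2)
            - log_norm
        )
        # Dirichlet part on rows with >= 2 positive components
        phi_b = phi.reshape(-1, 1, 1)
        psum = np.where(self.gsi_pos[None], comp, 0.0).sum(axis=2, keepdims=True)
        conc = phi_b * comp / psum                           # (B, n_gsi, K)
        dir_term = np.where(
            self.gsi_pos[None],
            (conc - 1.0) * self.gsi_logx[None] - gammaln(conc),
            0.0,
        ).sum(axis=2) + gammaln(phi_b[:, :, 0])
        return (pattern + np.where(self.gsi_multi[None], dir_term, 0.0)).sum(axis=1)

    # -- public evaluation ---------------------------------------------------

    def logp(self, X: np.ndarray) -> np.ndarray:
        """Joint log-posterior kernel for a batch (B, d) -> (B,)."""
        X = np.atleast_2d(X)
        p, lp = self.spec.unpack(X)
        if self.engine == "numba":
            lp = lp + self._logp_fast(p)
            if "p2" in self.components and self.n_gsi:
                lp = lp + self._p2_binom(p)
        else:
            fwd = self._forward(p)
            for val in self.component_logliks(p, fwd).values():
                lp = lp + val
        return np.where(np.isfinite(lp), lp, -np.inf)

    def logp_single(self, x: np.ndarray) -> float:
        return float(self.logp(x[None])[0])

    def logp_breakdown(self, x: np.ndarray) -> dict[str, float]:
        """Named component values at one point (for diagnostics and tests)."""
        p, lp = self.spec.unpack(x[None])
        fwd = self._forward(p)
        out = {"prior": float(lp[0])}
        for k, v in self.component_logliks(p, fwd).items():
            out[k] = float(v[0])
        return out

    def grad(self, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
        """Central-difference gradient via one batched evaluation."""
        d = self.spec.dim
        pts = np.repeat(x[None], 2 * d, axis=0)
        idx = np.arange(d)
        pts[idx, idx] += h
        pts[d + idx, idx] -= h
        vals = self.logp(pts)
        return (vals[:d] - vals[d:]) / (2.0 * h)

    def grad_many(self, X: np.ndarray, h: float = 1e-5,
                  mode: str = "forward") -> tuple[np.ndarray, np.ndarray]:
        """Gradients and values for several points in one batched call.

        X (M, d) -> (grad (M, d), logp (M,)).  ``mode`` selects central
        differences (2d+1 evaluations per point) or forward differences
        (d+1 evaluations; the default for sampling, where the force field
        only shapes the proposal while acceptance uses exact values).
        """
        M, d = X.shape
        idx = np.arange(d)
        if mode == "central":
            stride = 2 * d + 1
            pts = np.empty((M * stride, d))
            for i in range(M):
                base = i * stride
                pts[base:base + 2 * d] = X[i]
                pts[base + idx, idx] += h
                pts[base + d + idx, idx] -= h
                pts[base + 2 * d] = X[i]
            vals = self.logp(pts)
            grads = np.empty((M, d))
            lps = np.empty(M)
            for i in range(M):
                base = i * stride
                grads[i] = (vals[base:base + d] - vals[base + d:base + 2 * d]) / (2.0 * h)
                lps[i] = vals[base + 2 * d]
            return grads, lps
        if mode != "forward":
            raise ValueError(f"unknown gradient mode {mode!r}")
        stride = d + 1
        pts = np.empty((M * stride, d))
        for i in range(M):
            base = i * stride
            pts[base:base + d] = X[i]
            pts[base + idx, idx] += h
            pts[base + d] = X[i]
        vals = self.logp(pts)
        grads = np.empty((M, d))
        lps = np.empty(M)
        for i in range(M):
            base = i * stride
            lps[i] = vals[base + d]
            grads[i] = (vals[base:base + d] - lps[i]) / h
        return grads, lps
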