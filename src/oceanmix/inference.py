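"""Posterior sampling and convergence diagnostics.

The sampler is an adaptive Hamiltonian Monte Carlo: unconstrained
parameters (see :class:`oceanmix.model.ParameterSpec`), leapfrog dynamics
with a jittered number of steps, dual-averaged step size targeting a fixed
acceptance rate, and a dense metric — by default the inverse Hessian at
the posterior mode (Laplace), optionally refreshed from a warmup window,
with warmup-window-only and diagonal metrics as alternatives.  Gradients
come from batched finite differences of the batched log-posterior; since
the leapfrog integrator remains deterministic and time-reversible for any
fixed force field, Metropolis acceptance with the exact log-posterior
keeps the chain exactly invariant — gradient accuracy affects efficiency,
never correctness.

All chains advance together — one batched kernel call per leapfrog step
covers every chain's gradient — and the whole run is deterministic given
the seed (per-chain streams are spawned from one master seed sequence).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .data import ObservationBundle
from .index import RunConfig
from .likelihoods import VARIANTS
from .model import PosteriorKernel

logger = logging.getLogger(__name__)


class InitializationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Draw container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Labeled MCMC draws with chain structure.

    ``values`` has shape (chains, iterations, n_parameters) on the
    constrained scale; ``names`` is the flat naming scheme, e.g.
    ``pi[SFB,summer,MONT]``, ``f[MEN,fall,troll]``, ``U[total:KLT:2001]``.
    """

    values: np.ndarray
    names: list[str]
    variant: str
    seed: int
    warmup: int
    retained: int
    unconstrained: np.ndarray | None = None
    accept_rate: np.ndarray | None = None
    divergences: int = 0

    def __post_init__(self):
        if self.values.ndim != 3 or self.values.shape[2] != len(self.names):
            raise ValueError("values must be (chains, iterations, parameters)")

    @property
    def n_chains(self) -> int:
        return self.values.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.values.shape[1]

    def get(self, name: str) -> np.ndarray:
        return self.values[:, :, self.names.index(name)]

    def select(self, prefix: str) -> list[str]:
        return [n for n in self.names if n.startswith(prefix)]

    def rhat(self, rank_normalized: bool = True) -> pd.Series:
        vals = {
            n: split_rhat(self.values[:, :, i], rank_normalized=rank_normalized)
            for i, n in enumerate(self.names)
        }
        return pd.Series(vals, name="rhat")

    def ess(self) -> pd.Series:
        vals = {
            n: effective_sample_size(self.values[:, :, i])
            for i, n in enumerate(self.names)
        }
        return pd.Series(vals, name="ess")

    def summary(self, quantiles=(0.025, 0.5, 0.975)) -> pd.DataFrame:
        flat = self.values.reshape(-1, len(self.names))
        qs = np.quantile(flat, quantiles, axis=0)
        df = pd.DataFrame(
            {f"q{int(1000 * q) / 10}": qs[i] for i, q in enumerate(quantiles)},
            index=self.names,
        )
        df.insert(0, "mean", flat.mean(axis=0))
        return df

    def to_dataframe(self) -> pd.DataFrame:
        """Long format (chain, iteration, name, value)."""
        M, N, P = self.values.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(M), N * P),
                "iteration": np.tile(np.repeat(np.arange(N), P), M),
                "name": np.tile(self.names, M * N),
                "value": self.values.ravel(),
            }
        )

    def save(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def _rank_normalize(x: np.ndarray) -> np.ndarray:
    """Pooled fractional ranks mapped through the normal quantile function."""
    S = x.size
    r = rankdata(x.ravel(), method="average").reshape(x.shape)
    return ndtri((r - 0.375) / (S + 0.25))


def split_rhat(chains: np.ndarray, rank_normalized: bool = True) -> float:
    """Split-R-hat of one parameter from per-chain draw arrays (M, N).

    Each chain is split in half (2M sequences); with ``rank_normalized``
    the pooled draws are replaced by normal scores of their ranks before
    the classic between/within variance ratio is formed.  Returns NaN
    (with a warning) when total variance vanishes.
    """
    chains = np.atleast_2d(np.asarray(chains, float))
    M, N = chains.shape
    if M < 2 or N < 4:
        raise ValueError("need >= 2 chains and >= 4 draws per chain")
    half = N // 2
    split = np.concatenate([chains[:, :half], chains[:, N - half:]], axis=0)
    if np.ptp(split) == 0.0:
        logger.warning("split_rhat: zero total variance; returning NaN")
        return float("nan")
    if rank_normalized:
        split = _rank_normalize(split)
    W = split.var(axis=1, ddof=1).mean()
    B = half * split.mean(axis=1).var(ddof=1)
    if W == 0.0:
        logger.warning("split_rhat: zero within-chain variance; returning NaN")
        return float("nan")
    var_hat = (half - 1) / half * W + B / half
    return float(np.sqrt(var_hat / W))


def effective_sample_size(chains: np.ndarray) -> float:
    """Bulk effective sample size from rank-normalized split chains,
    using Geyer's initial monotone positive sequence of autocorrelations."""
    chains = np.atleast_2d(np.asarray(chains, float))
    M, N = chains.shape
    half = N // 2
    split = np.concatenate([chains[:, :half], chains[:, N - half:]], axis=0)
    if np.ptp(split) == 0.0:
        return float("nan")
    z = _rank_normalize(split)
    m, n = z.shape
    chain_means = z.mean(axis=1)
    zc = z - chain_means[:, None]
    # FFT autocovariance per chain
    size = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(zc, size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), size, axis=1)[:, :n].real / n
    W = (acov[:, 0] * n / (n - 1)).mean()
    var_hat = acov[:, 0].mean() * (n - 1) / n + (chain_means.var(ddof=1) if m > 1 else 0.0)
    rho = 1.0 - (W - acov.mean(axis=0)) / var_hat
    # Geyer initial monotone positive sequence of paired autocorrelations
    pair_sums: list[float] = []
    t = 0
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        if pair_sums and pair > pair_sums[-1]:
            pair = pair_sums[-1]
        pair_sums.append(pair)
        t += 2
    tau = -1.0 + 2.0 * sum(pair_sums)
    tau = max(tau, 1.0 / np.log10(n + 10))
    return float(m * n / tau)


def convergence_report(
    draws: PosteriorDraws, thresholds: Sequence[float] = (1.01, 1.1)
) -> dict:
    """Summary of convergence: median R-hat, fraction of parameters under
    each threshold, and the worst offenders by name."""
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError(f"thresholds must be strictly increasing: {thresholds}")
    rhat = draws.rhat().dropna()
    fractions = {thr: float((rhat < thr).mean()) for thr in thresholds}
    worst = rhat.sort_values(ascending=False).head(10)
    return {
        "median_rhat": float(rhat.median()),
        "fractions_below": fractions,
        "worst": worst,
        "n_parameters": int(len(rhat)),
    }


# ---------------------------------------------------------------------------
# Adaptive HMC
# ---------------------------------------------------------------------------

@dataclass
class HMCOptions:
    target_accept: float = 0.9
    leapfrog_range: tuple[int, int] = (10, 20)
    init_step_size: float = 0.05
    max_init_tries: int = 30
    jitter: float = 0.2
    fd_step: float = 1e-6
    fd_mode: str = "forward"
    max_energy_change: float = 1000.0
    # metric: "laplace" locates the posterior mode and uses the inverse
    # Hessian there as a fixed dense metric (decorrelating the strong
    # distribution/fishing-rate/entry-mortality ridges); "dense" estimates
    # the covariance from a warmup window instead; "diag" stays diagonal.
    metric: str = "laplace"
    shrinkage: float = 0.2
    map_maxiter: int = 600
    # re-estimate the metric from a warmup window (shrunk toward the
    # current metric); captures ridge scales the mode Hessian understates
    refresh_metric: bool = True


def _dual_averaging_update(state, accept_prob, target, t0=10.0, gamma=0.05, kappa=0.75):
    """One Nesterov dual-averaging step; state = (log_eps, log_eps_bar, H, mu, t)."""
    log_eps, log_eps_bar, H, mu, t = state
    t += 1.0
    H = (1.0 - 1.0 / (t + t0)) * H + (target - accept_prob) / (t + t0)
    log_eps = mu - np.sqrt(t) / gamma * H
    eta = t ** (-kappa)
    log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
    return (log_eps, log_eps_bar, H, mu, t)


def laplace_mode(
    kernel: PosteriorKernel, x0: np.ndarray, opt: HMCOptions
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior mode and a dense inverse-Hessian metric at the mode.

    Returns ``(x_map, Sigma, chol_S)`` with ``Sigma = chol_S @ chol_S.T``
    approximating the posterior covariance.  The Hessian is built column by
    column from finite differences of the batched gradient; its spectrum is
    floored to keep the metric positive definite even where the mode sits
    against a flat (prior-dominated) direction.
    """
    from scipy.optimize import minimize

    d = kernel.spec.dim

    def neg(x):
        g, lp = kernel.grad_many(x[None], h=opt.fd_step, mode=opt.fd_mode)
        return -lp[0], -g[0]

    res = minimize(neg, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": opt.map_maxiter, "maxcor": 25})
    x_map = res.x
    h = 1e-4
    pts = np.repeat(x_map[None], 2 * d, axis=0)
    idx = np.arange(d)
    pts[idx, idx] += h
    pts[d + idx, idx] -= h
    g_all, _ = kernel.grad_many(pts, h=opt.fd_step, mode=opt.fd_mode)
    H = (g_all[:d] - g_all[d:]) / (2.0 * h)      # rows: d(grad)/dx_i
    H = -0.5 * (H + H.T)                          # negative log-posterior curvature
    vals, vecs = np.linalg.eigh(H)
    floor = max(vals.max() * 1e-8, 1e-8)
    vals = np.maximum(vals, floor)
    Sigma = (vecs / vals) @ vecs.T
    chol_S = np.linalg.cholesky(
        Sigma + 1e-12 * np.eye(d) * Sigma.diagonal().max()
    )
    logger.info("Laplace mode: logp %.1f after %d evals (converged=%s)",
                -res.fun, res.nfev, res.success)
    return x_map, Sigma, chol_S


def run_hmc(
    kernel: PosteriorKernel,
    n_chains: int,
    warmup: int,
    retained: int,
    seed: int,
    options: HMCOptions | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Sample the kernel's posterior; returns (draws (M, retained, d),
    accept rates (M,), divergence count)."""
    opt = options or HMCOptions()
    spec = kernel.spec
    d = spec.dim
    master = np.random.SeedSequence(seed)
    chain_rngs = [np.random.Generator(np.random.PCG64(s))
                  for s in master.spawn(n_chains)]
    shared_rng = np.random.Generator(np.random.PCG64(master.spawn(1)[0]))

    # initialization with retries
    X = np.empty((n_chains, d))
    laplace = None
    if opt.metric == "laplace":
        x0 = spec.init_point(shared_rng, jitter=0.0)
        laplace = laplace_mode(kernel, x0, opt)
    for i, rng in enumerate(chain_rngs):
        ok = False
        for attempt in range(opt.max_init_tries):
            if laplace is not None:
                x_map, _, chol0 = laplace
                scale = 1.0 / (1.0 + 0.5 * attempt)
                x = x_map + scale * (chol0 @ rng.standard_normal(d))
            else:
                x = spec.init_point(rng, jitter=opt.jitter * (1.0 + 0.5 * attempt))
            if np.isfinite(kernel.logp_single(x)):
                X[i] = x
                ok = True
                break
        if not ok:
            breakdown = kernel.logp_breakdown(x)
            bad = [k for k, v in breakdown.items() if not np.isfinite(v)]
            raise InitializationError(
                f"chain {i}: could not find a finite starting point after "
                f"{opt.max_init_tries} tries; non-finite components: {bad}"
            )

    # metric: x-update uses Sigma (the inverse metric, ~ posterior
    # covariance); momenta are N(0, Sigma^{-1}).  With the Laplace metric,
    # Sigma is fixed at the inverse Hessian; otherwise it starts at the
    # identity and is re-estimated once from a warmup window.
    if laplace is not None:
        _, Sigma, chol_S = laplace
    else:
        Sigma = np.eye(d)
        chol_S = np.eye(d)        # Sigma = chol_S @ chol_S.T

    def draw_momentum():
        xi = np.stack([rng.standard_normal(d) for rng in chain_rngs])
        # p = L^{-T} xi so that p ~ N(0, Sigma^{-1})
        from scipy.linalg import solve_triangular

        return solve_triangular(chol_S.T, xi.T, lower=False).T

    def kinetic(P):
        tmp = P @ chol_S
        return 0.5 * (tmp * tmp).sum(axis=1)

    da = [
        (np.log(opt.init_step_size), np.log(opt.init_step_size), 0.0,
         np.log(10.0 * opt.init_step_size), 0.0)
        for _ in range(n_chains)
    ]
    eps = np.full(n_chains, opt.init_step_size)

    grads, lps = kernel.grad_many(X, h=opt.fd_step, mode=opt.fd_mode)
    total_iters = warmup + retained
    draws = np.empty((n_chains, retained, d))
    accepts = np.zeros(n_chains)
    divergences = 0
    win_lo, win_hi = max(1, int(0.2 * warmup)), max(2, int(0.7 * warmup))
    window: list[np.ndarray] = []

    for it in range(total_iters):
        L = int(shared_rng.integers(opt.leapfrog_range[0], opt.leapfrog_range[1] + 1))
        P = draw_momentum()
        H0 = -lps + kinetic(P)

        Xp, Pp = X.copy(), P.copy()
        gp = grads.copy()
        lpp = lps.copy()
        for step in range(L):
            Pp = Pp + 0.5 * eps[:, None] * gp
            Xp = Xp + eps[:, None] * (Pp @ Sigma)
            gp, lpp = kernel.grad_many(Xp, h=opt.fd_step, mode=opt.fd_mode)
            Pp = Pp + 0.5 * eps[:, None] * gp
        H1 = -lpp + kinetic(Pp)
        dH = H0 - H1
        dH = np.where(np.isfinite(dH), dH, -np.inf)
        diverged = dH < -opt.max_energy_change
        divergences += int(diverged.sum())
        accept_prob = np.exp(np.minimum(0.0, dH))
        u = np.array([rng.random() for rng in chain_rngs])
        accept = (u < accept_prob) & ~diverged

        X[accept] = Xp[accept]
        grads[accept] = gp[accept]
        lps[accept] = lpp[accept]

        if it < warmup:
            for i in range(n_chains):
                da[i] = _dual_averaging_update(
                    da[i], float(accept_prob[i]), opt.target_accept
                )
                eps[i] = float(np.exp(da[i][0]))
            refresh = opt.refresh_metric or laplace is None
            if refresh and win_lo <= it < win_hi:
                window.append(X.copy())
            if refresh and it == win_hi - 1 and len(window) >= 10:
                arr = np.concatenate(window, axis=0)      # (M * W, d)
                n_est = arr.shape[0]
                var = arr.var(axis=0, ddof=1)
                var = (n_est * var + 5.0) / (n_est + 5.0)
                if opt.metric in ("dense", "laplace") and n_est >= d // 2:
                    cov = np.cov(arr.T)
                    w = opt.shrinkage
                    cov = (1.0 - w) * cov + w * np.diag(np.diag(cov))
                    if laplace is not None:
                        # blend with the Laplace curvature: the window sees
                        # ridge scales, the Hessian sees local correlations
                        w_s = n_est / (n_est + 2.0 * d)
                        cov = w_s * cov + (1.0 - w_s) * Sigma
                    cov[np.diag_indices(d)] += 1e-8 * max(var.max(), 1.0)
                    try:
                        chol_S = np.linalg.cholesky(cov)
                        Sigma = cov
                    except np.linalg.LinAlgError:
                        Sigma = np.diag(np.maximum(var, 1e-8))
                        chol_S = np.sqrt(Sigma)
                else:
                    Sigma = np.diag(np.maximum(var, 1e-8))
                    chol_S = np.sqrt(Sigma)
                # restart step-size adaptation; the metric change rescales
                # the whole space, so begin from an O(0.1) whitened step
                for i in range(n_chains):
                    da[i] = (np.log(0.1), np.log(0.1), 0.0, np.log(1.0), 0.0)
                    eps[i] = 0.1
            if it == warmup - 1:
                eps = np.exp([s[1] for s in da])     # freeze at averaged value
        else:
            draws[:, it - warmup, :] = X
            accepts += accept

    return draws, accepts / max(retained, 1), divergences


# ---------------------------------------------------------------------------
# Fit entry point
# ---------------------------------------------------------------------------

def fit(
    data: ObservationBundle,
    config: RunConfig,
    variant: str = "cwt_gsi",
    seed: int | None = None,
    chains: int | None = None,
    warmup: int | None = None,
    retained: int | None = None,
    components: Iterable[str] | None = None,
    options: HMCOptions | None = None,
) -> PosteriorDraws:
    """Sample the posterior of a model variant for one observation bundle.

    ``variant`` is one of ``cwt_only`` (tag recoveries alone), ``cwt_gsi``
    (adds GSI compositions, focal proportions, run sizes, landings) or
    ``cwt_gsi_age`` (adds the multinomial age block).  ``components``
    overrides the variant's toggle set explicitly.  Chain settings default
    to the configuration's ``mcmc`` table; the result is deterministic
    given the seed.
    """
    if variant not in VARIANTS and components is None:
        raise ValueError(f"unknown variant {variant!r}")
    data.require_valid(config)
    comps = components if components is not None else variant
    kernel = PosteriorKernel(config, data, components=comps)
    mc = config.mcmc
    n_chains = chains if chains is not None else int(mc["chains"])
    n_warm = warmup if warmup is not None else int(mc["warmup"])
    n_ret = retained if retained is not None else int(mc["retained"])
    the_seed = int(seed if seed is not None else mc.get("seed", 0))

    t0 = time.time()
    raw, acc, ndiv = run_hmc(kernel, n_chains, n_warm, n_ret, the_seed, options)
    logger.info(
        "fit %s: %d chains x (%d + %d) in %.1f s; mean accept %.2f; %d divergences",
        variant, n_chains, n_warm, n_ret, time.time() - t0, acc.mean(), ndiv,
    )

    flat = raw.reshape(-1, kernel.spec.dim)
    constrained = kernel.spec.constrain(flat).reshape(n_chains, n_ret, -1)
    return PosteriorDraws(
        values=constrained,
        names=kernel.spec.constrained_names(),
        variant=variant if components is None else "custom",
        seed=the_seed,
        warmup=n_warm,
        retained=n_ret,
        unconstrained=raw,
        accept_rate=acc,
        divergences=ndiv,
    )


def sample_prior_draws(
    kernel: PosteriorKernel, n: int, seed: int
) -> np.ndarray:
    """Constrained prior draws (n, P) for prior-vs-posterior comparisons."""
    rng = np.random.default_rng(seed)
    X = kernel.spec.sample_prior(rng, size=n)
    return kernel.spec.constrain(X)
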