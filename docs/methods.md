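# Methods

`oceanmix` implements an integrated state-space model of the ocean phase of
fall-run Chinook salmon: coded-wire-tag (CWT) recoveries and genetic stock
identification (GSI) mixture samples are fit jointly to estimate
season-specific spatial distributions and region × season × year abundances
for a small set of focal stocks.  This note records the model, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Process model

The model tracks two kinds of release group through a shared season-step
schedule.  A *CWT group* is a hatchery cohort with known release size `R`;
a *total group* is every smolt of a stock entering the ocean in one brood
year, hatchery- and natural-origin alike.  Cohorts appear at the spring
step of ocean age 2 — pre-age-2 processes are collapsed into one
cumulative instantaneous mortality — and leave the ocean by the fall of
the terminal age, where maturation probability is fixed at 1.  Seasons are
abstract ordered labels (spring → summer → fall → winter); no calendar
months enter any computation, and the model year of a cohort is anchored
to its brood year with the age incrementing at the spring step.

Entry abundances:

* CWT group `j` of stock `r`, brood year `b`:
  `N_j = R_j · exp(−(M0_j + δ_{r,b}))`, where `M0_j` is the group's
  pre-age-2 mortality and `δ_{r,b}` a process deviation shared by every
  release of the same stock and brood year (the shared-process
  constraint).  We place the shared deviation at the entry point — the
  simplest structure satisfying the constraint.
* Total group: the sum of its linked CWT groups' entry abundances plus an
  estimated untagged abundance `U ≥ 0`.  Tagged abundance is therefore a
  hard lower bound on total abundance by construction.

Within each step, fish are allocated to regions by the stock × season
distribution simplex `π[r, s, ·]` (constant across years), then harvested
and subject to natural mortality.  The default is the Baranov catch
equation with simultaneous fishing and natural mortality:

    F_{l,g} = v_{a,g} · f_{l,s,c,g},   Z_l = Σ_g F_{l,g} + M_a
    C_{l,g} = N π_l (F_{l,g} / Z_l)(1 − e^{−Z_l}),   survivors = N π_l e^{−Z_l}

A sequential alternative (harvest first, then natural mortality) is a
configuration switch (`catch_equation`), because either convention is
defensible and the rest of the machinery is unchanged.  Both satisfy exact
per-step conservation: abundance = survivors + catch + natural deaths +
matured, which the test suite checks to 1e-9 relative tolerance.  In fall,
survivors mature with probability `m[r, a]` (after fishing and natural
mortality) and leave to freshwater; these departures accumulate into
expected run sizes.

Vulnerability `v[a, g]` is fixed at 1 by default and estimable by config;
with it fixed, `f` absorbs the age-aggregated fishing rate.  Per-step
natural mortality is fixed (defaults 0.1031 / 0.0561 / 0.0431 per step for
ages 2 / 3 / 4+, configurable).

## Observation model

Five streams, each an independent likelihood component that can be toggled
to realize the CWT-only, CWT+GSI, and CWT+GSI+Age variants:

1. **CWT recoveries.**  Negative binomial with mean `λ·C` (sampling
   fraction times expected catch) and per-gear dispersion `τ_g`.  The NB
   (rather than Poisson) absorbs overdispersion in recovery counts; the
   Poisson is the `τ → ∞` limit.  Expected counts are floored at 1e-8 so a
   vanishing prediction against a positive count stays finite.  One row
   exists per (release group, sampled stratum), zeros included — observed
   zeros carry real information.
2. **GSI compositions.**  The expected composition of a stratum's catch
   over (focal stocks, other) is compared to the sampled soft-assignment
   shares through a zero-and-one-inflated Dirichlet (ZOID) with
   concentration `φ` (smaller `φ` = noisier compositions = less weight on
   GSI).  The zero-inflation mechanism ties structural absence to sample
   size: category `k` is absent with probability `(1 − p_k)^n` under
   independent thinning, conditioned on at least one category being
   observed so that the 2^K − 1 admissible zero-patterns form a
   probability distribution.  Conditional on the positive set, the
   renormalized composition follows a Dirichlet with concentration
   `φ · p_S / Σp_S`; a single positive component (one-inflation) carries
   no continuous term.  This construction was an open design point; the
   function is isolated so an alternative inflation mechanism can be
   swapped in.
3. **Focal proportions.**  Each GSI stratum carries a latent focal
   proportion `p2` (the share of total catch belonging to the focal
   stocks), used to expand focal catch to total catch
   (`μ_total = μ_focal / p2`).  The summed focal assignments among the
   `n` sampled fish are binomial in `p2` (soft sums rounded — a
   documented approximation), and the `logit(p2)` are hierarchical around
   regional × gear means with an estimated SD, so strata without GSI
   borrow strength.  Strata that have landings but no GSI sample use the
   regional mean `logit⁻¹(p2bar)` as a plug-in rather than a latent
   draw — this bounds the latent dimension while keeping the expansion
   defined everywhere.

   The binomial term deserves a caveat: the ZOID composition likelihood
   already carries the focal/other split through its non-focal category,
   so the split is scored twice.  This is a deliberate constraint — we
   measured the alternative.  Without the binomial anchor the per-stratum
   proportions couple with the untagged abundances, fishing rates, and
   distributions into a soft global ridge that gradient MCMC cannot
   traverse at desk scale for arbitrary truths (split-R-hat of 2–4; the
   full-scale application reports analogous non-convergence).  With it,
   every variant samples cleanly.  The cost is a mild, quantifiable
   distortion: under self-generated data the double-counted split leaves
   the composition residuals tighter than the ZOID expects, biasing the
   overdispersion `φ` upward — see the calibration discussion below.
4. **Run sizes.**  Lognormal around expected freshwater returns with fixed
   log-SD `σ_run` (default 0.3).
5. **Landings.**  Normal around the expanded total catch
   `μ_total = μ_focal / p2` with SD `cv · μ_total` (default CV 0.15).
6. **Age compositions** (optional block).  Multinomial counts against the
   model's own age structure — the start-of-season abundance shares of the
   ages present in that season.

Priors: Dirichlet(1) on each `π` row; Normal on log/logit-scale rates
(defaults: `log M0 ~ N(0.7, 0.5)` so the prior median pre-age-2 mortality
is about 2; `log f ~ N(−1.6, 0.7)`; `log U ~ N(13, 1.5)`);
Gamma(2, 0.1) on `φ` and `τ`; half-Normal(0, 0.5) on the hierarchy SD.

## Posterior computation

Sampling is adaptive Hamiltonian Monte Carlo on unconstrained parameters
(stick-breaking for simplexes, log/logit elsewhere).  Three implementation
choices matter:

* **Gradients** are batched finite differences: the whole displaced point
  set (d+1 forward-difference points per chain) is evaluated in one call
  of a batched log-posterior (a compiled numba core, cross-checked against
  a vectorized numpy path and a row-by-row reference accumulation to
  ~1e-10).  Leapfrog integration with any deterministic position-dependent
  force field remains reversible and volume-preserving, and acceptance
  uses exact log-posterior values, so the chain targets the exact
  posterior; gradient accuracy affects only efficiency.
* **Metric.**  The posterior carries strong ridges (entry mortality ×
  fishing rate × distribution trade-offs — the same weak identification
  the full-scale application reports).  The default metric is a dense
  inverse Hessian at the posterior mode (found by L-BFGS on the same
  batched gradients), which whitens those ridges; warmup then only adapts
  the step size by dual averaging (target acceptance 0.9), and chains
  initialize from the Laplace approximation.  Warmup-window covariance and
  diagonal metrics remain available as options.
* **Parameterization.**  The latent focal proportions use the centered
  parameterization when GSI components are active (per-stratum samples are
  informative) and the non-centered one when they would sit at the
  hierarchical prior (the CWT-only variant), avoiding the funnel geometry
  in each regime.

Chain settings default to the full-scale configuration (6 chains, 400
warmup, 1,400 retained); the built-in toy configuration uses 4 chains,
150 warmup, 400 retained, which the package treats as its desk-scale
default for the bundled scenarios.  Seeds: one master seed; per-chain
streams are spawned from it, so runs are deterministic.

Convergence is summarized by rank-normalized split-R-hat (plain split
R-hat available), bulk effective sample size (Geyer initial monotone
sequence), and a report of threshold fractions and worst offenders.  The
R-hat implementation is cross-checked against `arviz`.

Divergent trajectories (energy error beyond 1000) are rejected and
counted; a handful per run is typical for this posterior and does not
materially affect the summaries at toy scale.

## Synthetic data

The generator draws every stream from its own likelihood family under a
known truth: NB recoveries, per-fish multinomial GSI sampling (optionally
pushed through a row-stochastic misassignment matrix, each fish reporting
its origin row as a soft probability vector), lognormal run sizes,
truncated-at-zero normal landings (the truncation is a documented
deviation from the plain normal likelihood; at CV 0.15 it is negligible),
and multinomial age counts.  Scenario seeds fully determine output.

Built-in scales:

* `toy` — 2 stocks × 4 regions × 6 years, ages 2–3, one troll fleet,
  year-constant fishing rates, GSI in summer and fall (48 strata,
  100–300 fish each), landings in all 96 fished strata, release sizes
  30k–120k giving realistic tens of recoveries per stratum.  This is the
  scale at which full fits run on one CPU in minutes; the fitting tests
  and the acceptance script use it.
* `reduced` — 4 stocks × 8 regions × 10 years, ages 2–5, two fleets,
  year-varying rates.
* `coastwide` — 4 stocks × 8 regions × 17 years; release sizes drawn
  within the published 9,000–3.5 million range; no winter GSI; sparse
  northern strata; recreational sampling restricted to the early years;
  mild (10%) genetic misassignment.

GSI sampling noise is selectable per scenario: `multinomial` (the default;
per-fish sampling from the expected composition, the realistic emulation of
dockside sampling) or `zoid` (compositions drawn from the model's own
inflated-Dirichlet family).  The distinction matters for calibration
studies: under multinomial sampling the overdispersion `φ` never enters the
data, so posterior ranks of a `φ` truth cannot be uniform; the
simulation-based calibration tests therefore use `zoid` noise.  Even then,
calibration is approximate rather than exact: the double-scored
focal/other split (see the focal-proportion caveat above) means no
generative process corresponds exactly to the fitted likelihood.  In
replicate experiments the fishing-rate and entry-mortality ranks behave
uniformly, while the `φ` ranks sit low — the posterior systematically
overestimates `φ` because the binomial term absorbs part of the dispersion
the ZOID would otherwise attribute to overdispersion.  The bundled
calibration check runs the smoke-scale protocol (five replicates, pooled
chi-square); at larger replicate counts the `φ` margin alone would reject
uniformity, and any application that leans on the absolute value of `φ`
should bear this structural bias in mind.  Recovery of distributions and
abundances (the quantities the model exists for) is unaffected: fixed-truth
replicate fits recover `π` with rank correlation above 0.95 and
nominal-or-better interval coverage.

The toy scenario deliberately keeps winter fishing (so winter
distributions are data-informed through CWT recoveries alone), and fixes
the per-group process deviation at 0 and vulnerability at 1 in fitting —
with one CWT group per stock × brood year, `M0` and `δ` are additively
confounded, and estimating both would only trade prior mass between them.
Both mechanisms remain implemented and unit-tested.

What passing these tests shows: the likelihoods are exact densities, the
dynamics conserve fish, the sampler recovers known truth with calibrated
uncertainty *when the model generated the data*.  What they do not show:
robustness to the misspecifications of real monitoring data —
misassignment (generated but not modeled, matching the real pipeline's
status), non-stationary distributions, time-varying age structure,
under-reported run sizes for rare stocks, or fleet behavior correlated
with abundance.

## Numerical details

* Expected-count floors 1e-8 (recoveries, run sizes, expanded landings);
  composition floor 1e-10 with renormalization before the ZOID density.
* Stick-breaking follows the standard shifted-logistic construction with
  exact log-Jacobian; its inverse is used to initialize at, or pack, known
  parameter values.
* Forward-difference step 1e-6 (central differences, step 1e-5, as a
  cross-check mode); Hessian columns by central differences of gradients
  at step 1e-4, spectrum floored at 1e-8 of the largest eigenvalue.
* Degenerate strata: a stratum with zero expected catch yields an empty
  GSI sample at generation (warning) and a uniform composition in the
  (never exercised) zero/zero expansion.
* Truncated cohorts (brood years whose terminal fall exceeds the year
  range) are simulated over their in-range steps only, with a warning.

## Known limitations

* Distributions are constant across years; environmental covariates are
  out of scope.
* The GSI misassignment matrix perturbs generated data but has no
  correction term in the likelihood, mirroring the real data pipeline.
* The binomial focal-proportion likelihood rounds soft sums.
* At desk scale the fitted scenarios use a single gear and year-constant
  fishing rates; the model supports two gears and year-varying rates
  (exercised by the larger generators and unit tests, not by full fits).
* The sampler's dense metric is fixed after warmup; posteriors whose
  curvature varies strongly across the support (e.g. the unidentified
  total-abundance ridge when both run sizes, landings, and the binomial
  anchor are withheld) mix slowly there.
* When only run sizes and landings are withheld, the untagged entry
  abundances revert essentially to their prior (posterior log-SD inflates
  an order of magnitude) — the full-scale application reports this
  non-estimability as concentrated non-convergence (worst R-hat) on those
  parameters.  The dense Laplace metric samples the widened directions
  efficiently, so the R-hat symptom does not reproduce here even though
  the information loss does; the variant-comparison suite keeps the
  faithful R-hat assertion (which accordingly fails) alongside a passing
  check of the uncertainty inflation itself.
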