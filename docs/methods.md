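# Methods

## The game and its analysis

The model is a three-strategy replicator system on the 2-simplex. Strategy
frequencies `(x_CC, x_TD, x_HD)` evolve by `dx_i/dt = x_i (π_i − π̄)` with
the payoffs given in the README. Analysis is restricted to the parameter
region `b − c > sb > 0`, `0 < s < 1`, `c > d > 0`: conditional cooperation
and honest defection are then mutually uninvadable (bistable), honest
defection dominates deception, and deception is cheaper than cooperation.
Parameter validation enforces these constraints at construction; the CLI
reports the violated inequality verbatim.

**Regime classification (constant q).** Deceivers dominate cooperators iff
`b(q + s − qs) − d > b − c`. The classifier computes the gap and raises a
degenerate-case error when it is within 1e-12 of zero rather than binning a
knife-edge silently. Under the constraint set the HD vertex is always a Nash
equilibrium; the CC vertex is Nash exactly when deceivers do not dominate.

**Invasion logic.** Pairwise invasion is computed from rare-mutant versus
resident payoffs at the resident's vertex, with `q` evaluated at the
resident's deceiver frequency in the frequency-dependent mode. One
consequence worth spelling out: a rare conditional cooperator among
deceivers earns `−cs` (detection is perfect at `x_TD = 1`, but the
cooperator still slips in fraction `s` of rounds) while resident deceivers
earn `−d`, so CC invades the TD population iff `d > cs`. Payoff ties within
1e-12 are flagged neutral, not counted as invasion.

**Mixed equilibrium (q = 1 − x_TD).** Payoff equality `π_CC = π_TD` on the
CC–TD edge reduces to `(b − c)(1 − s) t² − b(1 − s) t + (c − d) = 0` in
`t = x_TD`. The parabola opens upward in `π_TD − π_CC`; when `d > cs` the
endpoint signs differ and exactly one interior root exists, while for
`d < cs` there are either zero or two interior roots, of which only the
smaller-`t` one attracts along the edge (edge flow `t(1−t)(π_TD − π_CC)`
changes sign from + to − there). The finder solves the quadratic in closed
form, keeps the unique edge-attracting interior root (roots within 1e-10 of
0 or 1 are boundary equilibria, not mixtures), and raises a structural error
should more than one attracting interior root ever appear. Stability is then
assessed in the full simplex; the transverse eigenvalue against honest
defectors equals `d − b(1 − s)(x_CC*)²`, so the mixture resists HD invasion
iff `b(1 − s)(x_CC*)² > d`, which is reported as both a flag and a margin.

**Stability.** The Jacobian is taken in reduced coordinates `(x_CC, x_TD)`
with `x_HD = 1 − x_CC − x_TD`, by central differences at h = 1e-6 (the
right-hand side is cubic, so the finite-difference error is ~1e-12).
Eigenvalue real parts below −1e-8 count as stable, above +1e-8 as unstable,
and anything in between is reported as *marginal* — never silently binned.
Inputs whose replicator field exceeds 1e-8 are rejected as non-fixed-points.

**Integration.** `scipy.integrate.solve_ivp` (RK45, rtol 1e-8, atol 1e-10).
The replicator field conserves the simplex exactly; the numerical solution
may undershoot the boundary by roughly the absolute tolerance, so reported
states clip negatives no larger than `max(1e-12, 10·atol)` to zero and
renormalise, while larger violations abort with diagnostics. Trajectories
therefore satisfy `|Σx − 1| < 1e-9` and `x_i ≥ −1e-12` at every reported
time. The test suite checks endpoints against an independent fixed-step
Euler map at h = 1e-4.

**Sweep.** The (b, d) sweep solves the closed-form quadratic per cell (the
default grid is 200×200; tests and the acceptance script use 50×50, which
resolves the region boundaries to ~1% of the axis range). A cell records
`x_CC*` only when the mixture exists, is stable on the simplex, and resists
HD invasion; otherwise the reason (invalid parameters, no root, unstable,
HD-invadable) is kept per cell. An optional cache keyed by `(b, d, s, c)`
makes sweeps resumable.

**Reproduction parameter sets.** The dynamics figures are driven by
`b = 1.5, c = 0.5, s = 0.2` with `q = 0.8`, `q = 0.5` and `q = 1 − x_TD`.
The deception cost for these illustrations is a package choice: `d = 0.1`
for the collapse and stable-mixture regimes and `d = 0.45` for the bistable
regime, each satisfying the regime inequalities with room to spare. At
`d = 0.1 = cs` the worked mixture lands exactly at `x_CC* = 1/2`.

## The comparative stage

**Model.** Generalized least squares with error covariance proportional to
the shared-path-length (Brownian) matrix of the phylogeny — Pagel's λ fixed
at 1, no signal estimation, because λ estimates are unreliable at the sample
sizes this analysis targets (~24 species). The response is
`ln(deception count + 1)`; predictors are the 0–3 cooperativeness score, a
cognitive-capacity covariate (neocortex ratio, or ln neocortex volume), and
`ln(research effort)` to absorb observation effort. Natural logs throughout:
significance is base-invariant, coefficients scale by ln 10 ≈ 2.303 if a
user expects base-10. Research effort enters as a covariate with a free
coefficient rather than as a fixed offset, matching the model structures
above. An intercept is estimated; p-values are two-sided from the t
distribution on `n − k` degrees of freedom (the convention of the standard
PGLS software stacks).

**Implementation and cross-check.** The covariance matrix is built by a
single postorder pass (MRCA depth per tip pair); the solve is delegated to
`statsmodels.GLS`. Independently, Felsenstein's pruning algorithm is
implemented in full (contrast = daughter difference / √(summed adjusted
branch lengths); ancestral value = inverse-variance-weighted mean; parent
branch extended by the product-over-sum correction), and a through-origin
OLS on the standardized contrasts provides a second route to the same
coefficients, standard errors and t statistics. The suite asserts agreement
to 1e-8 across trees of 10–100 tips; in practice it is ~1e-13. Partialled
contrasts (for plotting the focal relationship) residualise response and
focal contrasts on the nuisance contrasts through the origin; the
Frisch–Waugh–Lovell identity ties their slope to the full-model coefficient
and is asserted in tests.

**Trees.** Newick I/O, pruning and polytomy handling are delegated to
dendropy. Trees explicitly marked unrooted are rejected; polytomies (common
in consensus trees) are accepted, flagged, and resolved to bifurcations with
zero-length internal edges — a transformation that leaves all tip-to-tip
path lengths, and hence every PGLS/contrast result, unchanged, so the
(seedable) resolution order is immaterial. Species names match after
canonicalization (underscores ↔ spaces, case-folded). Pruning requires at
least two retained taxa; zero summed daughter branch lengths at a contrast
node raise an error naming the node.

## The synthetic-data generator

The generator emulates the statistical structure the regression assumes, at
the scale of a primate comparative collation:

* **Tree:** Yule process, birth rate 1, simulated forward; in fixed-size
  mode the final inter-event time is allowed to elapse so pendant edges are
  positive. Depth of an n-tip tree is ≈ ln(n) time units.
* **Cooperativeness:** a latent Brownian trait cut at its 25/50/75%
  quantiles into {0, 1, 2, 3}, so the score is phylogenetically
  autocorrelated, as a sum of three conserved present/absent behaviours
  would be. Thresholds are configurable.
* **Brain covariates:** neocortex volume `exp(3 + w)` and ratio
  `exp(0.8 + 0.4 w)` share a latent Brownian trait `w` (rate 0.25), giving
  correlated, positive, plausibly primate-ranged values (ratios ~1–4).
* **Research effort:** iid log-normal counts (log-mean 4, log-sd 1,
  i.e. a median of ~55 publications), ceiling-rounded to ≥ 1.
* **Response:** latent `Σ β·predictor + BM(σ², rate 0.2) noise` with default
  β = (intercept 1.0, cooperativeness 0.9, log-effort 0.5); the deception
  count is `round(e^latent − 1)` floored at 0 — the exact inverse of the
  analysis transform — with a Poisson option for robustness experiments.

Everything is driven by NumPy's seeded PCG64 generator; a fixed seed fixes
the Newick string, the table and every downstream estimate (the round-trip
through CSV/Newick reproduces fits to 1e-12).

What the generator does *not* emulate: anecdotal observation bias in
deception records, measurement error in brain volumes, non-Brownian trait
evolution, and diversified or incomplete taxon sampling. Passing calibration
tests therefore show the estimator is correct *under its own assumptions* —
unbiased slope recovery (mean within ±0.05 of 0.9 at 100 tips) and a type-I
error near nominal (within [0.02, 0.08] at 24 species) — not that real
deception catalogues satisfy those assumptions. The count discretisation is
the one deliberate misspecification retained (real counts are integers); it
costs a few coverage points (≈91–96% empirical coverage for nominal 95%)
and is part of what the calibration experiments measure.

## Problem sizes and numerical defaults

Simulation-based checks use 120 parameter sets for the constant-q interior
scan (16 multistarts each plus the analytic candidate), 50×50 sweep grids,
20 datasets for the equivalence battery, 200 replicates at 100 tips for
recovery/coverage, 1000 replicates at 24 tips for type-I error, and 20
trajectories against the h = 1e-4 Euler oracle — sizes at which every
Monte-Carlo band in the tests is comfortably wider than its standard error
while the whole suite stays interactive (~30 s).

## Known limitations

* The game is deterministic and infinite-population; finite-population
  (Moran) dynamics, spatial structure, and mechanistic strategy spaces are
  out of scope.
* `q = 1 − x_TD` is the simplest negative-frequency-dependence scheme; other
  detection-learning curves would move the mixture's location, though not
  the qualitative structure.
* λ is fixed at 1 by design; the module does not estimate phylogenetic
  signal, and misspecified branch lengths propagate directly into the GLS
  weights.
* The two-interior-root regime (`d < cs`) coexists with a locally stable
  all-TD edge state; basins matter there, and the sweep reports only the
  attracting mixture.
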