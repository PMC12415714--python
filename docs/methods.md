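# Methods

## The problem

Mapping a rare disease over small administrative areas (the motivating case
is pleural mesothelioma over the ~2100 Danish parishes, 1990–2021) faces two
obstacles.  First, with a handful of cases per area, raw incidence rate
ratios are wildly unstable.  Second, the individual-level registry data that
such analyses rest on cannot be redistributed.  This package addresses both:
it implements the full analysis — indirect standardization, Bayesian spatial
smoothing, exceedance flagging, residual diagnostics — and pairs it with a
synthetic registry generator that reproduces the *shape* of the real data
(area-size distribution, stratum rates, spatially correlated risk, ICD-coded
records) so every stage is testable end to end.

## Model

For areas i = 1..n with observed counts O_i and expected counts E_i from
indirect age/sex standardization,

    O_i | φ ~ Poisson(E_i · exp(β + φ_i))
    φ ~ N(0, τ² [ρ(D − W) + (1 − ρ) I]⁻¹)          (Leroux CAR)
    β ~ N(0, V_β),  τ² ~ IG(a, b),  ρ ~ U[0, ρ_max)

W is the symmetric binary adjacency matrix (rook contiguity on lattices,
queen contiguity from polygons), D = diag(d_i) the degree matrix.  The
Leroux precision interpolates between independent heterogeneity (ρ = 0) and
the intrinsic CAR (ρ → 1) and is positive definite for every ρ ∈ [0, 1):
its eigenvalues are (ρλ_k + 1 − ρ)/τ² ≥ (1 − ρ)/τ² > 0, where λ_k are the
eigenvalues of the graph Laplacian D − W.  The full conditional of a single
effect is Gaussian with mean ρ Σ_{j~i} φ_j / (ρ d_i + 1 − ρ) and variance
τ² / (ρ d_i + 1 − ρ); islands (d_i = 0) are permitted and reduce to
N(0, τ²/(1 − ρ)).

The **smoothed IRR** is θ_i = exp(β + φ_i).  Because reference rates are
computed internally (Σ E_i = Σ O_i exactly), β sits near zero and θ_i is
read as area-to-national relative risk.  The alternative exp(φ_i) is
available (`irr_draws(..., include_intercept=False)`); the choice is
recorded in the run manifest.  An area is flagged at threshold c when
P(θ_i > c | data) > 0.95, both inequalities strict, with c ∈ {1.25, 2.0} by
default.

## Inference

Metropolis-within-Gibbs, deterministic given the seed:

* **φ**: one univariate random-walk Metropolis update per area, in index
  order, combining the Poisson term O_i φ_i − E_i e^{β+φ_i} with the
  Gaussian full conditional.  After each sweep φ is recentred (mean
  subtracted and absorbed into β): intercept plus proper CAR is only weakly
  identified, and recentring stabilises β without changing fitted risks
  E_i e^{β+φ_i}.  Recentring slightly perturbs the exact stationary law, so
  the exact-kernel validation below disables it; it is also skipped when β
  is held fixed, since β then cannot absorb the shift.
* **β**: random-walk Metropolis against the Poisson profile times N(0, V_β).
* **τ²**: exact conjugate draw IG(a + n/2, b + φᵀ[ρ(D−W)+(1−ρ)I]φ / 2),
  with the quadratic form computed by the edge-difference identity.
* **ρ**: random-walk Metropolis on the natural scale, proposals outside
  [0, ρ_max) rejected; the log-determinant uses
  log det[ρ(D−W)+(1−ρ)I] = Σ_k log(ρλ_k + 1 − ρ) with λ_k computed once per
  graph (dense symmetric eigendecomposition, adequate up to a few thousand
  areas), so each ρ proposal costs O(n).

Step sizes adapt by Robbins–Monro scaling (gain t^−0.6) toward 0.40
acceptance and freeze at the end of burn-in, preserving the correct
stationary law during sampling.  Defaults are burn-in 20 000, 100 000
sampling iterations thinned by 10, single chain; multi-chain runs use seed
offsets.  Non-finite log posteriors abort with a state dump.  Tests and the
acceptance script use much shorter profiles (stated below) chosen so each
posterior summary they assert is stable at the tolerance asserted.

Priors default to V_β = 100 000, τ² ~ IG(1, 0.01), ρ ~ U[0, 1) — the
defaults of the reference implementation for this model family — and are
fully configurable. `rho_max` (default 1.0) optionally bounds the ρ prior.

## Validation design

Three independent routes check the sampler:

1. **GMRF sampler**: the empirical covariance of 5·10⁴ Cholesky-based prior
   draws on a 3×3 lattice (ρ = 0.8, τ² = 1) is compared entrywise with the
   dense inverse of the Leroux precision, within 4 Monte-Carlo standard
   errors.
2. **Quadrature oracle**: on a 3-area path with ρ, τ², β fixed, posterior
   means of φ from the chain are compared (tolerance 0.02) against dense
   Riemann-grid integration of likelihood × prior, with a grid-refinement
   self-check (means must move < 10⁻³ when the step is halved).
3. **Getting-it-right**: draws of (β, φ, τ², ρ) from the prior are compared,
   by two-sample z-tests on first and second moments of ρ, τ² and φ_1, with
   draws produced by alternating a likelihood simulation with six exact MCMC
   transitions.  The successive chain's variance is inflated by its
   autocorrelation time.  This check needs priors with finite fourth
   moments, which the analysis defaults are not: IG(1, ·) has no finite
   mean, and with ρ ~ U[0, 1) the prior second moment of φ is infinite
   because the Leroux covariance scales as 1/(1 − ρ).  Validation therefore
   runs with τ² ~ IG(6, 5), β ~ N(0, 0.5), ρ ~ U[0, 0.95); the transition
   kernel being tested is identical under any prior.

## Synthetic registry generator

The generator defines the study conditions and is first-class, tested code:

* **Geography**: nx×ny rook lattices (or any supplied graph/GAL/GeoJSON).
* **Populations**: log-uniform on [31, 46 586], rescaled so the median is
  near 1039 — the printed range and median of Danish parish populations.
  Person-years are population × years (default 32, a 1990–2021 window),
  apportioned exactly over the 14 sex × age strata by a Danish-like pyramid.
  The generator emits person-years directly rather than reconstructing
  annual population dynamics.
* **Risk surface**: φ drawn exactly from the Leroux GMRF (Cholesky), with
  optional hotspot blocks whose φ is raised by log(multiplier); the truth
  object is serialisable for parameter-recovery scoring.
* **Stratum rates**: default to the Danish national pleural-mesothelioma
  rates per 100 000 person-years by sex and age group (e.g. male 71–80:
  16.84, female 71–80: 2.16).
* **Registry records**: one ICD-coded record per simulated case — mostly
  C45.0 (pleura), a minority C38.4 plus a mesothelioma ICD-O-3 morphology
  (M9050/3–M9053/3) — plus non-qualifying decoys (wrong site or morphology)
  at a configurable fraction of the true count, so the case-definition
  filter has a real decision boundary to get right.  Ages are drawn within
  the record's stratum (inclusive upper bin edges: 41–50 means
  41 ≤ age ≤ 50).
* A dataset-level seed is split into per-stage substreams
  (`numpy.random.SeedSequence.spawn`), so adding a stage never perturbs
  earlier draws.

What the generator does **not** emulate: real parish polygons and their
contiguity structure, residence histories and the ~27-year mean address
duration, diagnosis-date vs exposure-latency dynamics, and secular trends in
rates.  Passing tests therefore demonstrate correctness of the machinery
under a faithful-in-shape synthetic world, not epidemiological conclusions
about any real registry.

## Diagnostics

Pearson residuals z_i = (O_i − E_i θ̂_i)/√(E_i θ̂_i) of the posterior-mean
fit feed global Moran's I with row-standardized weights by default (binary
available); the analytic two-sided p uses the randomization-moment variance
(normality fallback at n = 3), and a permutation p (statistics centred at
the null expectation −1/(n−1)) is available.  Deviance residuals are a
documented alternative; the choice is logged in the manifest.  Chain health
is summarised by ESS (Geyer initial-positive-sequence truncation) and a
Geweke first-10%-vs-last-50% z with segment variances deflated by their own
ESS.

## Operating characteristics and a known limitation

Under a null surface (θ = 1, 15×15 lattice, E_i ≈ 5) fewer than 1% of areas
are flagged at (c = 1.25, p > 0.95), and false flags at c = 2.0 under a
hotspot scenario stay below 1%.  Sensitivity at c = 2.0 is bounded by
shrinkage: with a 9-area block at θ = 3 and E_i ≈ 10 embedded in a flat
background, the posterior spatial variance concentrates near 0.1 (most of
the field is flat), the prior precision of each φ_i then rivals the
likelihood precision, and the block's smoothed IRR is pulled to ≈ 1.9–2.4.
Typically only a minority of the nine areas exceeds the flagging rule at
c = 2.0 — even with counts fixed at their expectations — although the block
is fully flagged at c = 1.25.  This is the intended behaviour of CAR
smoothing (areas flagged at c = 2 need raw IRRs well above 3), not a sampler
defect: the same posterior is reproduced by the quadrature oracle.  Users
screening for moderate hotspots should read the c = 1.25 flags, or the
exceedance probabilities themselves, rather than the c = 2.0 flags.

## Numerical choices

* Rates are stored per person-year; the per-100 000 scale is display/I-O
  only.  Areas with E_i = 0 (possible in sparse synthetic worlds) are
  dropped from modelling with a warning and recorded in the manifest.
* Credible intervals are equal-tailed empirical quantiles with linear
  interpolation between order statistics.
* Laplacian eigenvalues below 10⁻¹² in magnitude are snapped to zero; the
  zero count equals the number of connected components.  Disconnected
  graphs are permitted; no bridging edges are invented.
* n = 1 graphs run as a pure Poisson-lognormal model; ρ then follows its
  prior.
* Degenerate Metropolis proposals (zero step) are accepted, as Δ = 0.

## Problem sizes used by the test suite and acceptance script

Conservation: 50 tables up to 200 areas.  GMRF check: 5·10⁴ draws, 9 areas.
Oracle check: 3·10⁴ retained draws on 3 areas.  Getting-it-right: 1.2·10⁴
draws per route on 6 areas.  Coverage: 20 replicates of a 15×15 lattice,
1000 retained draws each.  Flagging: 3 null + 5 hotspot replicates of the
15×15 lattice.  Moran calibration: 200 simulations × 199 permutations on a
6×6 lattice.  These sizes make every asserted quantity stable at its stated
tolerance while keeping a full run in minutes.
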