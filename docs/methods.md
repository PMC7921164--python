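# Methods

## The estimation problem

`pyadapt` estimates *time-dependent parameter trajectories* of a metabolic
state-space model

    dx/dt = N f(x, p, u),   x(0) = x0(p(0)),   y = g(x, f, p, u)

from longitudinal metabolite data, refined by longitudinal relative
gene-expression data.  The premise is that slow adaptations (disease
progression, drug response over days to weeks) act on the kinetic
parameters p — through enzyme abundance and post-translational control that
the metabolic model does not represent mechanistically — so structural
uncertainty about regulation is translated into a sequence of parameter
re-estimation problems.

The treatment period [0, T] is divided into N_t segments of length
Δt = T/N_t.  Starting from the baseline (untreated) parameter set p(0) and
the corresponding initial state, segment n is simulated with parameters
held at p(nΔt), initialized at the end state of segment n−1, and p(nΔt) is
chosen to minimize

    χ²(n) = χd²(n) + λg1 · χg1²(n) + λg2 · χg2²(n)

with three components:

* **Data term** χd² — the weighted SSE between the model outputs and
  continuous interpolants of the metabolite data, weights 1/σ², where σ is
  the measured SD linearly interpolated in time (floored at
  1e-6·|mean| + 1e-12).  By default outputs and interpolants are compared
  at the segment end node; a configurable number of collocation points per
  segment spreads the comparison over the segment interior (see *Numerical
  choices*).
* **Correlation reward** χg1² = Σᵢ Vᵢ, where for a parameter i coupled to
  N_ci genes, Vᵢ = (1/N_ci) Σⱼ (1 − ρᵢⱼ)², ρᵢⱼ being the Pearson
  correlation between the parameter's trajectory prefix p_i(0..nΔt) and the
  coupled gene's spline evaluated at the same nodes.  Uncoupled parameters
  contribute 0, as do prefixes with fewer than 3 nodes (a correlation over
  2 points is always ±1 and carries no information).  A (near-)constant
  series has no evidence of correlation; its ρ is defined as 0, giving the
  neutral penalty 1.
* **Fluctuation penalty** χg2² = Σᵢ Wᵢ with Wᵢ = (1/N_ci) Σⱼ (Pᵢ/Gᵢⱼ)² for
  coupled and Wᵢ = Pᵢ² for uncoupled parameters, where
  Pᵢ = (pᵢ(nΔt) − pᵢ((n−1)Δt)) / (Δt · pᵢ(0)) is the normalized parameter
  derivative and Gᵢⱼ = s′ᵢⱼ(nΔt)/dᵢⱼ(0) the normalized derivative of the
  coupled gene's spline, floored at |G| ≥ 1e-6 (sign preserved; an exact
  zero floors to +1e-6, immaterial since G enters squared).  Changing a
  parameter is costly unless its transcripts are themselves changing.

  The uncoupled branch is implemented *squared* (Wᵢ = Pᵢ²) so that the
  penalty is a proper sum of squares and a signed decrease is not
  *rewarded*; the sign-carrying form Wᵢ = Pᵢ is available via the
  `eq12_literal` switch, which routes the segment solve through a scalar
  quasi-Newton minimizer instead of the least-squares solver.

λg1, λg2 ≥ 0 are soft-constraint weights: gene data guide the trajectories
but can be overruled by the metabolic data (post-transcriptional control).

## Data model: Monte Carlo spline ensembles

Measurements are means ± SD over a handful of replicates at a few time
points.  Measurement uncertainty is propagated by an ensemble: each member
draws every data point independently from Normal(mean, SD) (truncated at 0
for concentrations and relative expression), fits one cubic smoothing
spline per observable through the draw, and the whole estimation runs once
per member.  The smoothing spline minimizes
q·Σ wᵢ(vᵢ − s(tᵢ))² + (1−q)·∫s″² with wᵢ = 1/SDᵢ² (floored); the default
smoothing level q = 1 interpolates each realization exactly with a natural
cubic spline, so the ensemble spread at the data times equals the
measurement spread.  Gene splines are refit per ensemble member, mirroring
the metabolic data treatment.  Splines are never evaluated outside the
data's time span.  Observables measured only at baseline take part in
baseline calibration but carry no spline.

## Baseline calibration

The untreated phenotype is calibrated by a global scatter search with
multistart refinement: parameter vectors are drawn log-uniformly over
[1e-6, 1e6] (intersected with the model bounds), ranked by the t = 0
weighted SSE, and the best 10% are polished with a bounded trust-region
least-squares solver (termination tolerances 1e-10, at most 1e3 iterations
and 1e5 evaluations).  Production defaults are 2×10⁵ draws; the benchmark
studies use 2×10³ (the toy problem has 7 parameters, and the top decile
converges to machine precision from far fewer starts).  The initial state
is declared in the model spec as expressions x0(p), which for the toy model
is its analytic steady state; baseline-only observables (e.g. a
compartment ratio) enter here.

## Ensembles, acceptance, grouping, variance reduction

A *scan* crosses spline samples with random (λg1, λg2) pairs drawn
log-uniformly, runs the full trajectory estimation for each and applies the
acceptance filter: a solution is accepted iff every measured output lies
within mean ± 1.96·SD at every measurement time (closed interval).  The
solutions at λ = (0, 0) form the unregularized reference group G0.
G_i denotes the fraction-i subset of accepted solutions with the lowest
χg1² summed over all segments (ties broken by run order; ⌊i·N⌋ members,
minimum 1).  The gene data's constraining effect on a quantity q is the
pointwise variance reduction VR(t) = 1 − Var_group(q(t))/Var_ref(q(t))
(reference variance floored at 1e-12; values reported unclipped).
Robust summaries (median, MAD, central-95% band) are computed pointwise
across members.

## Flux-route decomposition

For a designated pool (a subset of states, e.g. total hepatic TG), every
flux is classified by its net stoichiometric coefficient summed over the
pool states: positive → additive (F_a), negative → subtractive (F_s), zero
(internal transfers) → excluded, weighted by |net coefficient|.  By
construction F_a − F_s equals the pool's accumulation rate; the package
cross-checks this against a spline-differentiated state trajectory
(sup-norm, relative to the derivative's scale — pointwise ratios are
meaningless near zero crossings of the derivative).  Fractional
contributions fraction_k(t) = component_k(t)/F_a(t) are reported per flux
(optionally merged into named routes) and are undefined (not zero) where
F_a ≤ 0; time-to-peak is the argmax on the segment grid, earliest node on
ties.

## The synthetic benchmark

The generator emulates the structure of a three-week pharmacological
intervention study in a small cohort: ~7 observation times over 21 days
(0, 1, 2, 4, 7, 14, 21), N = 6 replicates summarized as mean ± SD,
metabolite CV 10%, relative gene expression normalized to 1 at t = 0 with
CV 5% (replicate-qPCR scale), smooth underlying dynamics.

The toy model has five states — plasma FFA, cytosolic TG, ER TG, plasma
VLDL-TG and a cleared-TG sink — eight mass-action fluxes and seven rate
constants (FFA influx, hepatic FFA uptake, de novo lipogenesis, cyt→ER
transfer, VLDL secretion, TG catabolism, VLDL clearance with a fixed 20%
hepatic re-uptake fraction).  It is a deliberately reduced caricature that
reproduces the structural motifs that matter for testing the method — a
compartment split observed only through its sum, flux observables, a
baseline-only ratio measurement, competing input routes with different
time signatures — not any published physiology.  Its baseline is the
analytic steady state, which makes all seven parameters structurally
identifiable from t = 0 data alone (states from the sum + ratio + plasma
measurements; rate constants from the three measured fluxes and the
steady-state relations).

Three canonical scenarios:

* **A — constant-parameter recovery.**  Truth is the stationary baseline.
  With noise-free data the pipeline must sit still (segment optimization
  starts at a stationary point); with CV 10% noise the 50-member ensemble
  must cover the truth.
* **B — latent-pool split.**  The cyt→ER transfer rate rises 2.5× and
  lipogenesis 3×, so hepatic TG accumulates ~40% and the accumulation is
  routed between cytosol and ER by the transfer rate.  The metabolic data
  constrain only the sum (plus baseline ratio), leaving a one-dimensional
  compensation manifold (transfer/secretion/catabolism) along which
  unregularized solutions drift; the rising transfer gene reports the true
  allocation.  The λ scan, χg1 grouping and variance reduction of the two
  pool states are exercised here.
* **C — route timing.**  The FFA-uptake rate steps up around day 1 (step
  width 0.3 d — as sharp as the daily observation grid can support;
  sub-resolution transitions only generate spline-interpolation artifacts,
  not recoverable timing signal) while lipogenesis ramps up over about a
  week; the uptake route's fractional contribution to the liver-TG pool
  peaks strictly before the lipogenesis route's, an ordering the flux
  decomposition must recover from noisy ensembles.  The route-timing
  ensemble runs at λ = (1.0, 1e-4), the operating point from the
  dose-response measurement where both gene terms are effective: the
  fluctuation penalty in particular suppresses early single-node parameter
  spikes that the (still flat) lipogenesis transcripts do not support.

Gene profiles are affine transforms of their parameter's relative
trajectory (configurable sign, strength, lag) plus replicate noise;
distractor genes are flat; a `decoupled` flag generates a gene that
contradicts its parameter, for probing the soft-constraint behavior.
Truth trajectories are integrated with piecewise-constant parameters on a
fine grid (10× the scenario's segment count by default; the discretization
error of this convention scales with the step, so derivative-sensitive
checks use a finer grid).

What passing on this benchmark does *not* show: performance under model
misspecification (the estimation model here *is* the generating model up
to parameter trajectories), non-Gaussian measurement error, irregular or
subject-specific sampling, and identifiability properties of larger
networks.

## Numerical choices

* **Integration** — stiff-capable adaptive solver (LSODA), absolute and
  relative tolerance 1e-6, configurable.  States are never clipped;
  excursions below −1e-8 are reported as diagnostics.  The right-hand side
  is guarded: a non-finite derivative or a state beyond 1e100 aborts
  immediately with the failing time and state named (stiff solvers
  otherwise grind indefinitely on diverging problems).
* **Optimization** — bounded trust-region-reflective least squares;
  termination tolerances 1e-10, iteration/evaluation caps 1e3/1e5.  The
  finite-difference step for the jacobian is 1e-3 (relative), on the order
  of the square root of the integration tolerance; the library default of
  ~1.5e-8 would make jacobians integrator-noise-dominated.
* **Collocation** — the package default compares model and interpolant at
  the segment end node only.  The benchmark studies run with 3 collocation
  points per segment: at the scaled-down segment counts used here
  (N_t = 21–50 versus a production-scale 200) the end-node-only subproblem
  is underdetermined (6 residuals, 7 parameters) and lets trajectories
  drift to the bounds within single segments — an artifact of the coarse
  Δt.  Three points pin the structurally identifiable directions while the
  latent pool-split direction remains free, which is the phenomenon under
  study.
* **λ ranges** — the scan draws λg1 ∈ [1e-4, 2] and λg2 ∈ [1e-12, 1e-4]
  log-uniformly.  These brackets were chosen from a dose-response
  measurement on the benchmark: χg1 becomes effective for λg1 ≳ 0.1 and
  saturates by ~2 (larger values degrade the data fit), while χg2 — whose
  terms are inflated by the 1e-6 gene-derivative floor — perturbs the fit
  for λg2 ≳ 1e-4.  Regularization weights are problem-dependent
  hyperparameters; the scan exists precisely to map the effective region
  of the problem at hand.
* **Scan pairing** — job j uses spline sample j mod n_samples; the study
  scans use a 40-sample ensemble with 40 dedicated λ = (0,0) runs, so each
  regularized run shares its spline sample with one unregularized run and
  group comparisons are paired (common random numbers).
* **Study sizes** — scatter 2×10³ draws (keep 10%), 200-run scans at
  N_t = 21 (Δt = 1 d, so the node grid contains every observation day),
  50-run recovery ensembles at N_t = 50, 40-run route-timing ensembles at
  N_t = 42 (Δt = 0.5 d).  Production defaults (N_t = 200, 2×10⁵ draws,
  100-sample ensembles) remain in `RunConfig`.
* **Determinism** — every random draw flows from `numpy` `SeedSequence`
  spawning; scan job seeds derive from the master seed and job index, so
  results are bitwise independent of worker count and execution order.

## Known limitations

* The greedy segment-by-segment optimization inherits path dependence:
  χg1² evaluates the correlation of a prefix whose past is frozen, so the
  achievable correlation depends on the order in which information
  arrives.
* The acceptance filter tests every (observable, time) pair at the
  per-point 95% interval; with ~36 independent Gaussian anchors per run
  the expected acceptance rate is bounded by 0.95³⁶ ≈ 16%, so small scans
  yield small accepted sets and the fraction-based groups can be very
  small.  This is a property of the filter's definition, not a bug; scale
  the scan up for tighter group statistics.
* With q = 1 splines (exact interpolation of each realization) the data
  term chases each realization's noise; the ensemble, not the single run,
  carries the uncertainty statement.
* Pointwise variance reduction compares finite-sample variances; for
  groups of only a few members it is a coarse instrument (a one-member
  group trivially reports VR = 1).  Where both variances are below the
  numerical floor (e.g. the shared t = 0 node), VR is defined as 0.
* Baseline calibration fits the data means, whose optimum on the toy
  benchmark is unique — all multistart fits coincide, so ensembles carry
  no baseline-parameter spread.  Resampling the t = 0 data per ensemble
  member would add it, at the cost of one calibration per member.
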