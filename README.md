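# pyadapt

Time-dependent parameter trajectory estimation for metabolic ODE models,
with transcriptome-guided regularization (the ADAPT method: Analysis of
Dynamic Adaptations in Parameter Trajectories).

## The problem

Slow metabolic adaptations — disease progression, a drug response over
weeks — act largely through regulation that kinetic metabolic models do
not describe mechanistically.  Instead of adding speculative regulatory
equations, ADAPT makes the kinetic parameters time-dependent and infers
*which parameters must change, and when*, to carry the model through
longitudinal metabolite data.  It works like a state observer: a
mechanistic model is driven by data and yields estimates of quantities
nobody measured — intracellular pool sizes, fluxes, rate constants — with
uncertainty bands from a Monte Carlo resampling of the data.

Gene-expression time courses enter as *soft constraints* on the estimation
rather than as model equations: a correlation reward (χg1²) prefers
parameter trajectories that co-move with their assigned transcripts, and a
derivative-weighted penalty (χg2²) makes parameter changes costly unless
the coupled transcripts are changing too.

## The method in one screen

The model is a state-space system `dx/dt = N f(x, p, u)`, `y = g(x, f, p)`
(stoichiometric matrix `N`, mass-action flux laws `f`, output map `g`).
The treatment period is split into `N_t` segments of length `Δt`; segment
`n` inherits the end state of segment `n−1` and re-estimates

    p̂(nΔt) = argmin  χd² + λg1·χg1² + λg2·χg2²

where

* `χd² = Σᵢ ((Yᵢ − dᵢ)/σᵢ)²` against cubic-smoothing-spline interpolants
  `d(t)` of the metabolite data (one spline ensemble member per Gaussian
  resample of the data),
* `χg1² = Σᵢ (1/N_ci) Σⱼ (1 − ρᵢⱼ)²` with `ρᵢⱼ` the Pearson correlation of
  parameter trajectory prefix and coupled gene spline,
* `χg2² = Σᵢ (1/N_ci) Σⱼ (Pᵢ/Gᵢⱼ)²` with normalized parameter and gene
  derivatives `P`, `G` (|G| floored at 1e-6).

Ensembles over spline samples and random `(λg1, λg2)` pairs are filtered
by a 95%-interval acceptance test, grouped by summed χg1² (`G_0.05` = the
5% most gene-correlated solutions), and compared by pointwise variance
reduction `VR = 1 − Var_group/Var_ref`.  A flux-route decomposition splits
a pool's net rate into additive and subtractive flux sums and reports each
route's fractional contribution and time-to-peak.

Everything is exercised end to end on a built-in synthetic benchmark (a
five-state hepatic-lipid toy model with known truth); see
`docs/methods.md` for the model, scenarios, and every numerical choice.

## Worked example

Estimate trajectories on the latent-pool benchmark scenario, in which the
cytosol→ER triglyceride transfer rate (`k_transfer`) rises 2.5× under
treatment and a coupled transfer gene reports it:

```python
import numpy as np
from pyadapt import (SolverSettings, accept, benchmark_suite,
                     build_ensemble, calibrate_baseline,
                     generate_gene_profiles, generate_observations,
                     generate_truth, run_adapt)

scen = benchmark_suite(0)["B"]
truth = generate_truth(scen)
obs = generate_observations(truth, scen, 7)      # mean±SD, 7 time points
genes = generate_gene_profiles(scen, 7)          # relative expression

fits = calibrate_baseline(scen.model, obs, n_scatter=2000,
                          keep_fraction=0.1, rng_seed=1)
print(f"baseline: {len(fits)} converged sets, best SSE = {fits[0].sse:.3g}")

m_ens = build_ensemble(obs, 1, 0)
g_ens = build_ensemble(genes, 1, 1)
sigma = {o: obs.sd_function(o) for o in obs.observables
         if o in scen.model.output_names}
sol = run_adapt(scen.model, fits[0].parameters, m_ens.splines[0], sigma,
                scen.coupling, g_ens.splines[0], (1.0, 1e-8),
                n_segments=21, t_end=21.0,
                settings=SolverSettings(collocation_points=3))
sol.accepted = accept(sol, obs)
i = scen.model.parameter_names.index("k_transfer")
print(f"accepted: {sol.accepted}")
print(f"chi_d2 sum = {sol.chi_sum('chi_d2'):.2f}, "
      f"chi_g1 sum = {sol.chi_sum('chi_g1'):.2f}")
print("k_transfer at days 0/7/14/21:",
      np.round(sol.parameters[i, [0, 7, 14, 21]], 3))
```

Output:

```
baseline: 200 converged sets, best SSE = 0
accepted: True
chi_d2 sum = 12.19, chi_g1 sum = 6.82
k_transfer at days 0/7/14/21: [0.272 1.017 0.715 0.905]
```

The baseline scatter search recovers the untreated steady state exactly
(SSE ≈ 0 against noise-free-identifiable baseline observables).  The run
is accepted (all outputs within the 95% interval of the data at every
measurement time), its summed data misfit and gene-correlation penalty are
reported per component, and the estimated `k_transfer` trajectory rises
from its baseline 0.3 toward the treated regime (true trajectory
0.3 → 0.75) — a single spline sample overshoots; the ensemble median and
bands, not one member, carry the uncertainty statement.

## Command line

The same pipeline is scriptable from the shell; each run archives its
effective configuration:

```sh
pyadapt synth --scenario B --out runB --seed 7     # benchmark data
pyadapt calibrate --config run.yaml                # baseline sets
pyadapt fit --config run.yaml                      # one trajectory run
pyadapt scan --config run.yaml                     # λ-scan ensemble
pyadapt analyze --ensemble-dir out --fraction 0.05 # grouping + VR
pyadapt report --ensemble-dir out --model-file runB/model.json \
    --pool tg_cyt,tg_er --out flux_report          # flux decomposition
```

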