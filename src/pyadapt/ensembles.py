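"""Monte Carlo ensembles of trajectory solutions: scan, filter, group, compare.

A solution ensemble crosses spline samples (data uncertainty) with random
(λg1, λg2) regularization pairs (hyperparameter uncertainty).  Solutions
whose outputs stray outside the 95% confidence interval of the data are
rejected; the remainder are grouped by their summed gene-correlation
penalty, and the effect of the gene data is quantified as a pointwise
reduction in ensemble variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .data import LongitudinalDataset, SplineEnsemble, sd_floor
from .estimation import (AdaptSolution, BaselineFit, GeneCouplingMap,
                         SolverSettings, run_adapt)
from .model import MetabolicModel

__all__ = [
    "SolutionEnsemble",
    "accept",
    "scan_lambdas",
    "group_by_correlation",
    "variance_reduction",
    "ensemble_summary",
    "save_ensemble",
]

#: floor for the reference variance in variance-reduction ratios
_VAR_FLOOR = 1e-12


def accept(solution: AdaptSolution, data: LongitudinalDataset) -> bool:
    """95%-confidence acceptance filter.

    True iff, for every measured metabolic observable and every
    measurement time, the model output lies within mean ± 1.96·sd
    (closed interval; SDs floored to keep the interval nonempty).
    """
    for i, obs in enumerate(data.observables):
        if data.kinds[i] != "metabolic":
            continue
        if obs not in solution.output_names:
            raise ValueError(
                f"observable {obs!r} has no matching model output")
        mask = np.isfinite(data.means[i])
        t = data.times[mask]
        mean = data.means[i, mask]
        sd = np.maximum(data.sds[i, mask], sd_floor(mean))
        y = solution.output_at(obs, t)
        if np.any(np.abs(y - mean) > 1.96 * sd):
            return False
    return True


@dataclass
class SolutionEnsemble:
    """Collection of trajectory solutions with their λ pairs."""

    solutions: list[AdaptSolution]
    lambda_grid: list[tuple[float, float]]
    rng_seed: int = 0

    def __post_init__(self):
        if len(self.solutions) != len(self.lambda_grid):
            raise ValueError("one λ pair per solution required")

    @property
    def n_runs(self) -> int:
        return len(self.solutions)

    def accepted(self) -> list[AdaptSolution]:
        return [s for s in self.solutions if s.accepted]

    def zero_lambda(self) -> list[AdaptSolution]:
        """The unregularized group G0: solutions run at λg1 = λg2 = 0."""
        return [s for s in self.solutions
                if s.lambda_pair == (0.0, 0.0) and s.accepted]

    def acceptance_rate(self, runs: Sequence[AdaptSolution] | None = None
                        ) -> float:
        runs = self.solutions if runs is None else list(runs)
        if not runs:
            return float("nan")
        return sum(bool(s.accepted) for s in runs) / len(runs)


def _resolve_model(model_dict_json: str) -> MetabolicModel:
    # models hold compiled (unpicklable) callables, so parallel workers
    # rebuild them from the serialized spec; cached per process
    cache = _resolve_model.__dict__.setdefault("_cache", {})
    if model_dict_json not in cache:
        cache[model_dict_json] = MetabolicModel.from_dict(
            json.loads(model_dict_json))
    return cache[model_dict_json]


def _scan_job(model_json: str, job_index: int, lam: tuple[float, float],
              baseline_p: np.ndarray, spline_sample, sigma_fns,
              coupling: GeneCouplingMap, gene_curves,
              n_segments: int, t_end: float, settings: SolverSettings,
              sample_index: int, baseline_index: int, seed: int,
              accept_data: LongitudinalDataset) -> AdaptSolution:
    model = _resolve_model(model_json)
    try:
        sol = run_adapt(model, baseline_p, spline_sample, sigma_fns,
                        coupling, gene_curves, lam, n_segments, t_end,
                        settings, spline_sample_index=sample_index,
                        baseline_index=baseline_index, rng_seed=seed)
        sol.accepted = accept(sol, accept_data)
    except Exception:
        # a failed run is recorded as an unaccepted placeholder
        sol = AdaptSolution(
            node_times=np.linspace(0, t_end, n_segments + 1),
            parameters=np.full((model.n_parameters, n_segments + 1), np.nan),
            states=np.full((n_segments + 1, model.n_states), np.nan),
            outputs=np.full((n_segments + 1, len(model.outputs)), np.nan),
            fluxes=np.full((n_segments + 1, model.n_fluxes), np.nan),
            objective_per_segment=[], lambda_pair=lam,
            spline_sample_index=sample_index, baseline_index=baseline_index,
            rng_seed=seed, accepted=False,
            flagged_segments=list(range(1, n_segments + 1)),
            parameter_names=list(model.parameter_names),
            state_names=list(model.state_names),
            output_names=list(model.output_names),
            flux_names=list(model.flux_names))
    return sol


def scan_lambdas(model: MetabolicModel, baseline_fits: list[BaselineFit],
                 ensemble: SplineEnsemble, coupling: GeneCouplingMap,
                 gene_ensemble: SplineEnsemble, data: LongitudinalDataset,
                 n_runs: int, rng_seed: int,
                 lambda_ranges: tuple[tuple[float, float],
                                      tuple[float, float]] = ((1e-4, 2.0),
                                                              (1e-12, 1e-4)),
                 n_zero_runs: int = 0, n_segments: int = 200,
                 t_end: float = 21.0,
                 settings: SolverSettings | None = None,
                 n_jobs: int = 1) -> SolutionEnsemble:
    """Run the trajectory estimator for random (λg1, λg2) combinations.

    ``n_zero_runs`` of the ``n_runs`` total are dedicated λ = (0, 0) runs
    (the unregularized reference group G0); the rest draw λ pairs
    log-uniformly over ``lambda_ranges``.  Each run pairs a λ pair with a
    spline sample (cycling through the ensemble) and a calibrated
    baseline set.  Every job's seed derives from the master seed and the
    job index, so results are identical whatever the worker count.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if n_zero_runs > n_runs:
        raise ValueError("n_zero_runs cannot exceed n_runs")
    settings = settings or SolverSettings()
    model_json = json.dumps(model.to_dict(), sort_keys=True)
    metab = data.subset("metabolic")
    sigma_fns = {obs: metab.sd_function(obs)
                 for obs in metab.observables
                 if obs in model.output_names}

    jobs = []
    for j in range(n_runs):
        child = np.random.SeedSequence(rng_seed, spawn_key=(j,))
        rng = np.random.default_rng(child)
        if j < n_zero_runs:
            lam = (0.0, 0.0)
        else:
            (lo1, hi1), (lo2, hi2) = lambda_ranges
            lam = (float(10 ** rng.uniform(np.log10(lo1), np.log10(hi1))),
                   float(10 ** rng.uniform(np.log10(lo2), np.log10(hi2))))
        s_idx = j % ensemble.n_samples
        b_idx = int(rng.integers(len(baseline_fits)))
        g_idx = s_idx % gene_ensemble.n_samples
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        jobs.append((j, lam, baseline_fits[b_idx].parameters,
                     ensemble.splines[s_idx], gene_ensemble.splines[g_idx],
                     s_idx, b_idx, seed))

    runner = Parallel(n_jobs=n_jobs)
    sols = runner(
        delayed(_scan_job)(model_json, j, lam, bp, sample, sigma_fns,
                           coupling, genes, n_segments, t_end, settings,
                           s_idx, b_idx, seed, metab)
        for j, lam, bp, sample, genes, s_idx, b_idx, seed in jobs)
    return SolutionEnsemble(list(sols), [j[1] for j in jobs],
                            rng_seed=int(rng_seed))


def group_by_correlation(ensemble: SolutionEnsemble, fraction: float
                         ) -> list[AdaptSolution]:
    """The fraction-``i`` group G_i of accepted solutions.

    Returns the ⌊i·N⌋ accepted solutions (minimum 1) with the lowest
    χg1² summed over the whole period, i.e. the highest temporal
    correlation with the gene data.  Ties break by run order (stable).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    accepted = ensemble.accepted()
    if not accepted:
        raise ValueError("no accepted solutions to group")
    count = max(1, int(np.floor(fraction * len(accepted))))
    order = sorted(range(len(accepted)),
                   key=lambda k: (accepted[k].chi_sum("chi_g1"), k))
    return [accepted[k] for k in order[:count]]


def _trajectories(solutions: Sequence[AdaptSolution], quantity: str,
                  eval_times) -> tuple[np.ndarray, np.ndarray]:
    if not solutions:
        raise ValueError("empty solution set")
    base_t = solutions[0].node_times
    eval_times = base_t if eval_times is None else np.asarray(
        eval_times, dtype=float)
    rows = np.empty((len(solutions), eval_times.size))
    for k, s in enumerate(solutions):
        v = s.quantity(quantity)
        rows[k] = np.interp(eval_times, s.node_times, v)
    return eval_times, rows


def variance_reduction(group: Sequence[AdaptSolution],
                       reference: Sequence[AdaptSolution], quantity: str,
                       eval_times=None) -> np.ndarray:
    """VR(t) = 1 − Var_group(q(t)) / Var_reference(q(t)) per time point.

    Positive values mean the group's estimate of the quantity is tighter
    than the reference's; the reference variance is floored to keep the
    ratio finite.  Values are returned unclipped (they can be negative).
    Time points where neither set has any spread (both variances below
    the floor, e.g. a shared fixed initial condition) report 0: no
    spread, no reduction.
    """
    _, g = _trajectories(group, quantity, eval_times)
    _, r = _trajectories(reference, quantity, eval_times)
    var_g = g.var(axis=0, ddof=1) if g.shape[0] > 1 else np.zeros(g.shape[1])
    var_r = r.var(axis=0, ddof=1) if r.shape[0] > 1 else np.zeros(r.shape[1])
    vr = 1.0 - var_g / np.maximum(var_r, _VAR_FLOOR)
    vr[(var_g < _VAR_FLOOR) & (var_r < _VAR_FLOOR)] = 0.0
    return vr


def ensemble_summary(solutions: Sequence[AdaptSolution], quantity: str,
                     eval_times=None) -> pd.DataFrame:
    """Robust pointwise summaries of a quantity across solutions.

    Returns a frame with the median, median absolute deviation, the
    central-95% band (2.5/97.5 empirical quantiles) and the variance at
    each evaluation time.
    """
    t, rows = _trajectories(solutions, quantity, eval_times)
    med = np.median(rows, axis=0)
    mad = np.median(np.abs(rows - med), axis=0)
    return pd.DataFrame({
        "time": t,
        "median": med,
        "mad": mad,
        "q2.5": np.quantile(rows, 0.025, axis=0),
        "q97.5": np.quantile(rows, 0.975, axis=0),
        "variance": (rows.var(axis=0, ddof=1) if rows.shape[0] > 1
                     else np.zeros(t.size)),
    })


def save_ensemble(ensemble: SolutionEnsemble, directory: str | Path,
                  quantities: Sequence[str] | None = None,
                  reference: Sequence[AdaptSolution] | None = None,
                  group: Sequence[AdaptSolution] | None = None) -> None:
    """Write manifest, per-solution tables, summaries and a VR matrix."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_runs": ensemble.n_runs,
        "rng_seed": ensemble.rng_seed,
        "acceptance_rate": ensemble.acceptance_rate(),
        "solutions": [],
    }
    for k, sol in enumerate(ensemble.solutions):
        stem = f"solution_{k:05d}"
        sol.save(directory / "solutions", stem)
        manifest["solutions"].append(
            {"index": k, **sol.manifest(),
             "trajectory_table": f"solutions/{stem}.csv"})
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n")

    if quantities:
        accepted = ensemble.accepted()
        frames = []
        for q in quantities:
            df = ensemble_summary(accepted, q)
            df.insert(0, "quantity", q)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(
            directory / "summary.csv", index=False)
        if reference is not None and group is not None:
            vr = {q: variance_reduction(group, reference, q)
                  for q in quantities}
            t = ensemble.solutions[0].node_times
            out = pd.DataFrame(vr, index=t)
            out.index.name = "time"
            out.to_csv(directory / "variance_reduction.csv")


def load_ensemble(directory: str | Path) -> SolutionEnsemble:
    """Rebuild a solution ensemble written by :func:`save_ensemble`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    solutions = []
    for entry in manifest["solutions"]:
        csv_path = directory / entry["trajectory_table"]
        solutions.append(AdaptSolution.load(
            csv_path, csv_path.with_suffix(".json")))
    return SolutionEnsemble(
        solutions, [s.lambda_pair for s in solutions],
        rng_seed=int(manifest["rng_seed"]))
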