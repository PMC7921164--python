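"""Segment-wise estimation of time-dependent parameter trajectories.

The treatment period [0, T] is split into ``N_t`` segments of length Δt.
Starting from a calibrated baseline parameter set p(0) and state x0(p(0)),
each segment n re-estimates the parameter vector by minimizing

    χ²(p(nΔt)) = χd² + λg1·χg1² + λg2·χg2²

where χd² is the weighted SSE between the model outputs at the segment end
node and the Monte Carlo data interpolants, χg1² rewards temporal Pearson
correlation between each parameter trajectory prefix and its coupled
gene-expression profiles, and χg2² penalizes normalized parameter changes,
relaxed in proportion to the (floored) normalized derivative of the coupled
gene splines.  The previous segment's estimate seeds the optimizer and its
end state seeds the integration, so trajectories chain forward in time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .data import Curve, LongitudinalDataset, sd_floor
from .model import MetabolicModel, simulate, simulate_segment

__all__ = [
    "GeneCouplingMap",
    "ObjectiveBreakdown",
    "AdaptSolution",
    "SolverSettings",
    "BaselineFit",
    "chi_d2",
    "pearson",
    "correlation_objective",
    "normalized_param_derivative",
    "normalized_gene_derivative",
    "fluctuation_objective",
    "total_objective",
    "calibrate_baseline",
    "estimate_segment",
    "run_adapt",
]

#: floor applied to |G_ij|, the normalized gene-derivative (division guard)
GENE_DERIVATIVE_FLOOR = 1e-6
#: floor for baseline normalizers p_i(0) and d_t(0)
BASELINE_FLOOR = 1e-12
#: minimum prefix length (nodes) for a defined trajectory correlation
MIN_CORR_WINDOW = 3


# ---------------------------------------------------------------------------
# coupling map

class GeneCouplingMap:
    """Assignment of transcripts to kinetic parameters.

    A parameter may be coupled to zero or more genes (a cascade of
    processes lumped into one rate law can inherit all of their genes);
    a gene may serve several parameters.
    """

    def __init__(self, couples: Sequence[tuple[str, str]],
                 sign_expectation: dict[tuple[str, str], str] | None = None):
        couples = [(str(p), str(g)) for p, g in couples]
        if len(set(couples)) != len(couples):
            raise ValueError("duplicate parameter-gene couples")
        self.couples = couples
        self.sign_expectation = dict(sign_expectation or {})
        self._by_param: dict[str, list[str]] = {}
        for p, g in couples:
            self._by_param.setdefault(p, []).append(g)

    def genes_for(self, parameter: str) -> list[str]:
        return list(self._by_param.get(parameter, []))

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(g for _, g in self.couples))

    @property
    def parameters(self) -> list[str]:
        return list(self._by_param)

    def validate(self, model: MetabolicModel,
                 gene_names: Sequence[str]) -> None:
        genes = set(gene_names)
        for p, g in self.couples:
            if p not in model.parameter_names:
                raise ValueError(f"coupled parameter {p!r} not in model")
            if g not in genes:
                raise ValueError(f"coupled gene {g!r} not in transcript data")

    # -- I/O (CSV with columns parameter, gene) ------------------------------

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.couples, columns=["parameter", "gene"]).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GeneCouplingMap":
        df = pd.read_csv(path)
        return cls(list(zip(df["parameter"], df["gene"])))


# ---------------------------------------------------------------------------
# objective components

@dataclass
class ObjectiveBreakdown:
    """The three objective components of one segment, plus their weights."""

    chi_d2: float
    chi_g1: float
    chi_g2: float
    lambda_g1: float
    lambda_g2: float

    @property
    def total(self) -> float:
        return (self.chi_d2 + self.lambda_g1 * self.chi_g1
                + self.lambda_g2 * self.chi_g2)


def chi_d2(y: Sequence[float], d: Sequence[float],
           sigma: Sequence[float]) -> float:
    """Weighted SSE between model outputs and data interpolants."""
    y, d, sigma = (np.asarray(a, dtype=float) for a in (y, d, sigma))
    if not y.shape == d.shape == sigma.shape:
        raise ValueError("y, d and sigma must have equal length")
    return float(np.sum(((y - d) / sigma) ** 2))


def pearson(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson correlation with a neutral fallback for degenerate series.

    When either series has (near-)zero variance there is no evidence of
    correlation and 0 is returned, which yields the neutral penalty
    (1-0)² = 1 in the correlation objective.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need two equal-length series of >= 2 points")
    da, db = a - a.mean(), b - b.mean()
    sa = np.sqrt(np.mean(da ** 2))
    sb = np.sqrt(np.mean(db ** 2))
    eps_a = 1e-12 * max(1.0, np.max(np.abs(a)))
    eps_b = 1e-12 * max(1.0, np.max(np.abs(b)))
    if sa < eps_a or sb < eps_b:
        return 0.0
    rho = float(np.mean(da * db) / (sa * sb))
    return min(1.0, max(-1.0, rho))


def correlation_objective(p_prefix: np.ndarray,
                          gene_prefix: dict[str, np.ndarray],
                          coupling: GeneCouplingMap,
                          parameter_names: Sequence[str]) -> float:
    """χg1² over a trajectory prefix p[·n].

    ``p_prefix`` has shape (n_params, n+1); ``gene_prefix`` maps gene
    names to the coupled splines evaluated at the same node times.
    Uncoupled parameters contribute 0, as do prefixes too short for a
    meaningful correlation (fewer than 3 nodes).
    """
    p_prefix = np.asarray(p_prefix, dtype=float)
    if p_prefix.shape[1] < MIN_CORR_WINDOW:
        return 0.0
    val = 0.0
    for i, name in enumerate(parameter_names):
        genes = coupling.genes_for(name)
        if not genes:
            continue
        val += np.mean([
            (1.0 - pearson(p_prefix[i], gene_prefix[g])) ** 2 for g in genes])
    return float(val)


def normalized_param_derivative(p_n: float, p_prev: float, p_0: float,
                                dt: float) -> float:
    """P_i = (p(nΔt) − p((n−1)Δt)) / (Δt · p(0)) with a floored normalizer."""
    return (p_n - p_prev) / (dt * max(abs(p_0), BASELINE_FLOOR))


def normalized_gene_derivative(gene_spline: Curve, gene_baseline: float,
                               t_eval: float) -> float:
    """G_ij = s'(t)/d(0), with |G| floored at 1e-6 preserving sign.

    An exactly zero derivative is floored to +1e-6 (the sign choice is
    immaterial since G enters the objective squared).
    """
    g = gene_spline.derivative(t_eval) / max(abs(gene_baseline),
                                             BASELINE_FLOOR)
    if abs(g) < GENE_DERIVATIVE_FLOOR:
        g = GENE_DERIVATIVE_FLOOR if g >= 0 else -GENE_DERIVATIVE_FLOOR
    return float(g)


def fluctuation_objective(p_n: Sequence[float], p_prev: Sequence[float],
                          p_0: Sequence[float], dt: float,
                          gene_derivs: dict[str, float],
                          coupling: GeneCouplingMap,
                          parameter_names: Sequence[str],
                          literal_uncoupled: bool = False) -> float:
    """χg2², the derivative-weighted parameter-fluctuation penalty.

    ``gene_derivs`` maps gene names to their floored normalized
    derivatives G_ij at the segment end node.  Coupled parameters
    contribute mean_j (P_i/G_ij)²; uncoupled parameters contribute P_i²
    by default (``literal_uncoupled=True`` switches to the unsquared,
    sign-carrying form).
    """
    p_n, p_prev, p_0 = (np.asarray(a, dtype=float)
                        for a in (p_n, p_prev, p_0))
    val = 0.0
    for i, name in enumerate(parameter_names):
        P = normalized_param_derivative(p_n[i], p_prev[i], p_0[i], dt)
        genes = coupling.genes_for(name)
        if genes:
            val += np.mean([(P / gene_derivs[g]) ** 2 for g in genes])
        else:
            val += P if literal_uncoupled else P ** 2
    return float(val)


def total_objective(chi_d2_val: float, chi_g1_val: float, chi_g2_val: float,
                    lambda_g1: float, lambda_g2: float) -> ObjectiveBreakdown:
    """Assemble the regularized objective, keeping components separate."""
    if lambda_g1 < 0 or lambda_g2 < 0:
        raise ValueError("regularization constants must be nonnegative")
    return ObjectiveBreakdown(float(chi_d2_val), float(chi_g1_val),
                              float(chi_g2_val), float(lambda_g1),
                              float(lambda_g2))


# ---------------------------------------------------------------------------
# solver settings

@dataclass
class SolverSettings:
    """Numerical settings shared by baseline and segment estimation.

    Defaults follow common practice for this estimator family: integration
    tolerances 1e-6, optimizer termination tolerances 1e-10, at most 1e3
    iterations and 1e5 function evaluations.
    """

    rtol: float = 1e-6
    atol: float = 1e-6
    ode_method: str = "LSODA"
    ftol: float = 1e-10
    xtol: float = 1e-10
    gtol: float = 1e-10
    max_iterations: int = 1000
    max_evaluations: int = 100_000
    eq12_literal: bool = False
    #: finite-difference step for the optimizer jacobian, relative; kept
    #: near sqrt(integration tolerance) so derivative estimates are not
    #: dominated by integrator noise
    diff_step: float = 1e-3
    #: data-term collocation points per segment (1 = end node only)
    collocation_points: int = 1


# ---------------------------------------------------------------------------
# baseline calibration

@dataclass
class BaselineFit:
    """One converged baseline parameter set with its goodness of fit."""

    parameters: np.ndarray
    sse: float
    start_index: int
    converged: bool


def _baseline_residual_fn(model: MetabolicModel, data: LongitudinalDataset):
    """Residuals of the t=0 outputs against the t=0 data."""
    if not np.isclose(data.times[0], 0.0):
        raise ValueError("baseline calibration expects data starting at t=0")
    out_idx, targets, sigmas = [], [], []
    for i, obs in enumerate(data.observables):
        if obs not in model.output_names:
            continue
        if not np.isfinite(data.means[i, 0]):
            continue
        out_idx.append(model.output_names.index(obs))
        targets.append(data.means[i, 0])
        sigmas.append(max(data.sds[i, 0], sd_floor(data.means[i, 0])))
    if not out_idx:
        raise ValueError("no model outputs covered by t=0 data")
    out_idx = np.asarray(out_idx)
    targets = np.asarray(targets)
    sigmas = np.asarray(sigmas)

    def residual(p: np.ndarray) -> np.ndarray:
        x0 = model.initial_state(p)
        y = model.output_values(x0, p, 0.0)
        return (y[out_idx] - targets) / sigmas

    return residual, len(out_idx)


def calibrate_baseline(model: MetabolicModel, data: LongitudinalDataset,
                       n_scatter: int = 200_000, keep_fraction: float = 0.1,
                       rng_seed: int = 0,
                       scatter_range: tuple[float, float] = (1e-6, 1e6),
                       settings: SolverSettings | None = None
                       ) -> list[BaselineFit]:
    """Scatter-search + multistart least squares for the untreated phenotype.

    Draws ``n_scatter`` parameter vectors log-uniformly over the scatter
    range (intersected with the model bounds), ranks them by the t=0
    weighted SSE, and polishes the best ``keep_fraction`` with a bounded
    trust-region least-squares solver.  Returns all converged fits sorted
    by final SSE (stable in draw order).
    """
    settings = settings or SolverSettings()
    residual, n_res = _baseline_residual_fn(model, data)
    if n_res < model.n_parameters:
        import warnings
        warnings.warn(
            f"only {n_res} baseline residuals for {model.n_parameters} "
            "parameters; the t=0 fit may be underdetermined")

    lb = np.maximum(model.parameter_bounds[:, 0], scatter_range[0])
    ub = np.minimum(model.parameter_bounds[:, 1], scatter_range[1])
    rng = np.random.default_rng(rng_seed)
    draws = np.exp(rng.uniform(np.log(lb), np.log(ub),
                               size=(n_scatter, model.n_parameters)))

    sse = np.empty(n_scatter)
    for k in range(n_scatter):
        r = residual(draws[k])
        sse[k] = np.sum(r ** 2) if np.all(np.isfinite(r)) else np.inf

    n_keep = max(1, int(round(n_scatter * keep_fraction)))
    order = np.argsort(sse, kind="stable")[:n_keep]

    fits, failures = [], []
    blb, bub = model.parameter_bounds[:, 0], model.parameter_bounds[:, 1]
    for k in order:
        try:
            res = least_squares(
                residual, draws[k], bounds=(blb, bub), method="trf",
                ftol=settings.ftol, xtol=settings.xtol, gtol=settings.gtol,
                max_nfev=settings.max_evaluations)
        except Exception as exc:  # singular start, overflow...
            failures.append(f"start {k}: {exc}")
            continue
        if res.status <= 0:
            failures.append(f"start {k}: {res.message}")
            continue
        fits.append(BaselineFit(res.x, float(2 * res.cost), int(k), True))
    if not fits:
        raise RuntimeError(
            "baseline calibration: no local run converged; diagnostics: "
            + "; ".join(failures[:10]))
    fits.sort(key=lambda f: (f.sse, f.start_index))
    return fits


# ---------------------------------------------------------------------------
# segment estimation and the full run

def _segment_residual_parts(model, out_idx, d_vec, sig_vec):
    def data_residual(y):
        return (y[out_idx] - d_vec) / sig_vec
    return data_residual


def estimate_segment(model: MetabolicModel, x_prev: np.ndarray,
                     p_prev: np.ndarray, p_prefix: np.ndarray,
                     spline_sample: dict[str, Curve],
                     sigma_fns: dict[str, callable],
                     coupling: GeneCouplingMap,
                     gene_curves: dict[str, Curve],
                     lambdas: tuple[float, float],
                     segment_index: int, dt: float,
                     p_baseline: np.ndarray,
                     gene_node_values: dict[str, np.ndarray] | None = None,
                     settings: SolverSettings | None = None):
    """Re-estimate the parameter vector for segment ``segment_index``.

    Returns ``(p_hat, x_end, y_end, f_end, breakdown, converged)``.  The
    optimizer starts from the previous segment's estimate; a solver
    failure returns the best iterate flagged as unconverged rather than
    aborting (the ensemble acceptance filter deals with bad runs).
    """
    if segment_index < 1:
        raise ValueError("segment_index must be >= 1")
    settings = settings or SolverSettings()
    lam1, lam2 = lambdas
    if lam1 < 0 or lam2 < 0:
        raise ValueError("regularization constants must be nonnegative")
    n = segment_index
    t_start, t_end = (n - 1) * dt, n * dt
    p_prev = np.asarray(p_prev, dtype=float)
    p_prefix = np.asarray(p_prefix, dtype=float)
    names = model.parameter_names

    measured = [obs for obs in model.output_names if obs in spline_sample]
    out_idx = np.asarray([model.output_names.index(o) for o in measured])
    n_col = max(1, settings.collocation_points)
    t_col = t_start + dt * np.arange(1, n_col + 1) / n_col
    t_col[-1] = t_end  # guard against one-ulp overshoot of the span
    d_mat = np.asarray([[spline_sample[o](t) for o in measured]
                        for t in t_col])
    sig_mat = np.asarray([[sigma_fns[o](t) for o in measured]
                          for t in t_col])

    # gene terms: node values for the correlation prefix, end-node
    # derivatives for the fluctuation penalty
    use_g1 = lam1 > 0 and coupling.couples and n + 1 >= MIN_CORR_WINDOW
    use_g2 = lam2 > 0
    if gene_node_values is None and coupling.couples:
        node_t = np.arange(n + 1) * dt
        gene_node_values = {g: gene_curves[g](node_t)
                            for g in coupling.genes}
    gene_prefix = ({g: np.asarray(v)[: n + 1]
                    for g, v in gene_node_values.items()}
                   if coupling.couples else {})
    gene_derivs = {
        g: normalized_gene_derivative(
            gene_curves[g], float(gene_node_values[g][0]), t_end)
        for g in coupling.genes} if coupling.couples else {}

    g1_terms = []  # (param_row, gene, weight)
    g2_coupled = []  # (param_row, gene, weight)
    g2_free = []  # param rows without genes
    for i, name in enumerate(names):
        genes = coupling.genes_for(name)
        if genes:
            w = 1.0 / len(genes)
            for g in genes:
                g1_terms.append((i, g, np.sqrt(lam1 * w)))
                g2_coupled.append((i, g, np.sqrt(lam2 * w)))
        else:
            g2_free.append(i)

    p0_floored = np.maximum(np.abs(p_baseline), BASELINE_FLOOR)

    def simulate_candidate(p):
        """(data residual matrix, x_end, y_end, f_end) for one candidate."""
        res = simulate(model, x_prev, p, (t_start, t_end), t_col,
                       rtol=settings.rtol, atol=settings.atol,
                       method=settings.ode_method)
        r_data = (res.outputs[:, out_idx] - d_mat) / sig_mat
        return r_data, res.states[-1], res.outputs[-1], res.fluxes[-1]

    def residual(p):
        r_data, _, y, _ = simulate_candidate(p)
        parts = [r_data.ravel()]
        if use_g1:
            r = np.empty(len(g1_terms))
            for k, (i, g, w) in enumerate(g1_terms):
                prefix = np.append(p_prefix[i], p[i])
                r[k] = w * (1.0 - pearson(prefix, gene_prefix[g]))
            parts.append(r)
        if use_g2:
            P = (p - p_prev) / (dt * p0_floored)
            if g2_coupled:
                parts.append(np.asarray(
                    [w * P[i] / gene_derivs[g] for i, g, w in g2_coupled]))
            if g2_free:
                parts.append(np.sqrt(lam2) * P[np.asarray(g2_free)])
        return np.concatenate(parts)

    lb, ub = model.parameter_bounds[:, 0], model.parameter_bounds[:, 1]
    p_start = np.clip(p_prev, lb, ub)
    converged = True
    if settings.eq12_literal and use_g2:
        # the literal (sign-carrying) uncoupled penalty is not a sum of
        # squares; fall back to a scalar quasi-Newton minimizer
        def scalar(p):
            r_data, _, _, _ = simulate_candidate(p)
            cd = float(np.sum(r_data ** 2))
            cg1 = correlation_objective(
                np.hstack([p_prefix, p[:, None]]), gene_prefix, coupling,
                names) if use_g1 else 0.0
            cg2 = fluctuation_objective(
                p, p_prev, p_baseline, dt, gene_derivs, coupling, names,
                literal_uncoupled=True)
            return cd + lam1 * cg1 + lam2 * cg2

        res = minimize(scalar, p_start, method="L-BFGS-B",
                       bounds=list(zip(lb, ub)),
                       options={"maxiter": settings.max_iterations,
                                "ftol": settings.ftol})
        p_hat, converged = res.x, bool(res.success)
    else:
        try:
            res = least_squares(
                residual, p_start, bounds=(lb, ub), method="trf",
                ftol=settings.ftol, xtol=settings.xtol, gtol=settings.gtol,
                diff_step=settings.diff_step,
                max_nfev=settings.max_evaluations)
            p_hat, converged = res.x, res.status > 0
        except Exception:
            p_hat, converged = p_start, False

    r_data, x_end, y_end, f_end = simulate_candidate(p_hat)
    cd = float(np.sum(r_data ** 2))
    if coupling.couples and n + 1 >= MIN_CORR_WINDOW:
        cg1 = correlation_objective(
            np.hstack([p_prefix, p_hat[:, None]]), gene_prefix, coupling,
            names)
    else:
        cg1 = 0.0
    cg2 = fluctuation_objective(
        p_hat, p_prev, p_baseline, dt, gene_derivs, coupling, names,
        literal_uncoupled=settings.eq12_literal)
    breakdown = total_objective(cd, cg1, cg2, lam1, lam2)
    return p_hat, x_end, y_end, f_end, breakdown, converged


@dataclass
class AdaptSolution:
    """One full estimated run: trajectories over the segment grid."""

    node_times: np.ndarray
    parameters: np.ndarray  # (n_params, N_t + 1)
    states: np.ndarray      # (N_t + 1, n_states)
    outputs: np.ndarray     # (N_t + 1, n_outputs)
    fluxes: np.ndarray      # (N_t + 1, n_fluxes)
    objective_per_segment: list[ObjectiveBreakdown]
    lambda_pair: tuple[float, float]
    spline_sample_index: int = 0
    baseline_index: int = 0
    rng_seed: int = 0
    accepted: bool | None = None
    flagged_segments: list[int] = field(default_factory=list)
    parameter_names: list[str] = field(default_factory=list)
    state_names: list[str] = field(default_factory=list)
    output_names: list[str] = field(default_factory=list)
    flux_names: list[str] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return self.node_times.size - 1

    def chi_sum(self, component: str) -> float:
        """Sum of one objective component over all segments."""
        return float(sum(getattr(b, component)
                         for b in self.objective_per_segment))

    def quantity(self, name: str) -> np.ndarray:
        """Trajectory of a named parameter, state, output or flux.

        Sums of states/fluxes are accepted as ``"a+b"`` expressions, which
        covers pooled quantities such as a total metabolite pool.
        """
        if "+" in name:
            parts = [self.quantity(p.strip()) for p in name.split("+")]
            return np.sum(parts, axis=0)
        for names, arr, axis in (
                (self.parameter_names, self.parameters, 0),
                (self.state_names, self.states, 1),
                (self.output_names, self.outputs, 1),
                (self.flux_names, self.fluxes, 1)):
            if name in names:
                i = names.index(name)
                return arr[i] if axis == 0 else arr[:, i]
        raise KeyError(f"unknown quantity {name!r}")

    def output_at(self, observable: str, times) -> np.ndarray:
        """Model output linearly interpolated from the node grid."""
        y = self.quantity(observable)
        return np.interp(np.asarray(times, dtype=float), self.node_times, y)

    # -- persistence ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.node_times})
        for i, n in enumerate(self.parameter_names):
            df[n] = self.parameters[i]
        for arr, names in ((self.states, self.state_names),
                           (self.outputs, self.output_names),
                           (self.fluxes, self.flux_names)):
            for i, n in enumerate(names):
                df[n] = arr[:, i]
        for comp in ("chi_d2", "chi_g1", "chi_g2"):
            col = np.full(self.node_times.size, np.nan)
            col[1:] = [getattr(b, comp) for b in self.objective_per_segment]
            df[comp] = col
        return df

    def manifest(self) -> dict:
        return {
            "lambda_g1": self.lambda_pair[0],
            "lambda_g2": self.lambda_pair[1],
            "n_segments": self.n_segments,
            "t_end": float(self.node_times[-1]),
            "spline_sample_index": self.spline_sample_index,
            "baseline_index": self.baseline_index,
            "rng_seed": int(self.rng_seed),
            "accepted": self.accepted,
            "flagged_segments": list(self.flagged_segments),
            "chi_d2_sum": self.chi_sum("chi_d2"),
            "chi_g1_sum": self.chi_sum("chi_g1"),
            "chi_g2_sum": self.chi_sum("chi_g2"),
            "parameter_names": list(self.parameter_names),
            "state_names": list(self.state_names),
            "output_names": list(self.output_names),
            "flux_names": list(self.flux_names),
        }

    def save(self, directory: str | Path, stem: str) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / f"{stem}.csv", index=False)
        manifest = self.manifest()
        manifest["trajectory_table"] = f"{stem}.csv"
        (directory / f"{stem}.json").write_text(
            json.dumps(manifest, indent=2) + "\n")

    @classmethod
    def load(cls, csv_path: str | Path, manifest_path: str | Path
             ) -> "AdaptSolution":
        """Rebuild a solution from its trajectory table and manifest."""
        m = json.loads(Path(manifest_path).read_text())
        df = pd.read_csv(csv_path, float_precision="round_trip")
        times = df["time"].to_numpy()
        lam = (float(m["lambda_g1"]), float(m["lambda_g2"]))
        breakdowns = [
            ObjectiveBreakdown(row.chi_d2, row.chi_g1, row.chi_g2, *lam)
            for row in df.iloc[1:].itertuples()]
        return cls(
            node_times=times,
            parameters=df[m["parameter_names"]].to_numpy().T,
            states=df[m["state_names"]].to_numpy(),
            outputs=df[m["output_names"]].to_numpy(),
            fluxes=df[m["flux_names"]].to_numpy(),
            objective_per_segment=breakdowns,
            lambda_pair=lam,
            spline_sample_index=int(m["spline_sample_index"]),
            baseline_index=int(m["baseline_index"]),
            rng_seed=int(m["rng_seed"]),
            accepted=m["accepted"],
            flagged_segments=list(m["flagged_segments"]),
            parameter_names=list(m["parameter_names"]),
            state_names=list(m["state_names"]),
            output_names=list(m["output_names"]),
            flux_names=list(m["flux_names"]))


def run_adapt(model: MetabolicModel, baseline_p: np.ndarray,
              spline_sample: dict[str, Curve],
              sigma_fns: dict[str, callable],
              coupling: GeneCouplingMap | None = None,
              gene_curves: dict[str, Curve] | None = None,
              lambdas: tuple[float, float] = (0.0, 0.0),
              n_segments: int = 200, t_end: float = 21.0,
              settings: SolverSettings | None = None,
              spline_sample_index: int = 0, baseline_index: int = 0,
              rng_seed: int = 0, x0: np.ndarray | None = None
              ) -> AdaptSolution:
    """Run the full segment-wise trajectory estimation.

    Iterates :func:`estimate_segment` for n = 1..N_t, chaining states and
    parameter estimates, and records per-segment objective breakdowns
    (all three components are evaluated even for the unregularized λ=0
    path, so solutions can later be grouped by their gene correlation).
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    settings = settings or SolverSettings()
    coupling = coupling or GeneCouplingMap([])
    gene_curves = gene_curves or {}
    baseline_p = np.asarray(baseline_p, dtype=float)
    dt = t_end / n_segments
    node_times = np.linspace(0.0, t_end, n_segments + 1)

    if x0 is None:
        x0 = model.initial_state(baseline_p)
    params = np.empty((model.n_parameters, n_segments + 1))
    states = np.empty((n_segments + 1, model.n_states))
    outputs = np.empty((n_segments + 1, len(model.outputs)))
    fluxes = np.empty((n_segments + 1, model.n_fluxes))
    params[:, 0] = baseline_p
    states[0] = x0
    outputs[0] = model.output_values(x0, baseline_p, 0.0)
    fluxes[0] = model.flux_values(x0, baseline_p, 0.0)

    gene_node_values = {g: gene_curves[g](node_times)
                        for g in coupling.genes}

    breakdowns, flagged = [], []
    for n in range(1, n_segments + 1):
        p_hat, x_n, y_n, f_n, bd, ok = estimate_segment(
            model, states[n - 1], params[:, n - 1], params[:, :n],
            spline_sample, sigma_fns, coupling, gene_curves, lambdas,
            n, dt, baseline_p, gene_node_values=gene_node_values,
            settings=settings)
        params[:, n] = p_hat
        states[n] = x_n
        outputs[n] = y_n
        fluxes[n] = f_n
        breakdowns.append(bd)
        if not ok:
            flagged.append(n)

    return AdaptSolution(
        node_times=node_times, parameters=params, states=states,
        outputs=outputs, fluxes=fluxes, objective_per_segment=breakdowns,
        lambda_pair=(float(lambdas[0]), float(lambdas[1])),
        spline_sample_index=spline_sample_index,
        baseline_index=baseline_index, rng_seed=int(rng_seed),
        flagged_segments=flagged,
        parameter_names=list(model.parameter_names),
        state_names=list(model.state_names),
        output_names=list(model.output_names),
        flux_names=list(model.flux_names))
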