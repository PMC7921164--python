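"""State-space representation of metabolic reaction networks.

A model is the system

    dx/dt = N f(x, p, u),   x(t0) = x0(p),   y = g(x, f, p, u)

with stoichiometric matrix ``N``, mass-action (or arbitrary closed-form)
flux laws ``f``, kinetic parameters ``p``, optional constant external
inputs ``u`` and an output map ``g`` onto the experimentally observed
quantities.  Flux laws and outputs are declared as strings in a JSON model
spec and compiled once with sympy; simulation uses scipy's stiff-capable
initial-value solvers with absolute and relative tolerances of 1e-6 by
default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

__all__ = [
    "MetabolicModel",
    "SimulationResult",
    "IntegrationError",
    "ModelSpecError",
    "simulate",
    "simulate_segment",
]

#: states flagged below this value are reported as negativity diagnostics
NEGATIVE_STATE_FLOOR = -1e-8


class ModelSpecError(ValueError):
    """Malformed model specification (unknown symbol, shape mismatch...)."""


class IntegrationError(RuntimeError):
    """ODE integration failure, naming the first failing time and state."""

    def __init__(self, message: str, time: float | None = None,
                 state: str | None = None):
        super().__init__(message)
        self.time = time
        self.state = state


def _flux_expression(entry: dict) -> str:
    """Return the rate expression for one flux-spec entry.

    Two declarative forms are supported: mass action
    (``parameter × coefficient × product of substrates``) and a free-form
    ``expr`` escape hatch.
    """
    if "expr" in entry:
        return entry["expr"]
    if "parameter" not in entry:
        raise ModelSpecError(
            f"flux {entry.get('name', '?')!r} needs 'expr' or 'parameter'")
    terms = [entry["parameter"]]
    coeff = entry.get("coefficient", 1)
    if coeff != 1:
        terms.insert(0, repr(float(coeff)))
    terms.extend(entry.get("substrates", []))
    return "*".join(terms)


@dataclass
class MetabolicModel:
    """A metabolic state-space model.

    Parameters
    ----------
    state_names, parameter_names
        Identifiers for the state variables x and kinetic parameters p.
    stoichiometry
        Integer matrix of shape (n_states, n_fluxes).
    fluxes
        Flux-spec entries (dicts with ``name`` plus either mass-action
        fields or ``expr``); order matches the stoichiometry columns.
    outputs
        Output-spec entries (dicts with ``name`` and ``expr``); expressions
        may reference states, parameters, inputs and flux names.
    parameter_bounds
        Array (n_params, 2) of lower/upper bounds; lower bounds must be
        nonnegative (rate constants).
    baseline_guess
        Optional nominal parameter vector used as an optimizer hint.
    initial_states
        Per-state expressions over the parameters realizing the x0(p(0))
        convention, or None if initial values are always supplied
        explicitly.
    inputs
        Constant external inputs u as a name→value mapping.
    """

    state_names: list[str]
    parameter_names: list[str]
    stoichiometry: np.ndarray
    fluxes: list[dict]
    outputs: list[dict]
    parameter_bounds: np.ndarray
    baseline_guess: np.ndarray | None = None
    initial_states: list[str] | None = None
    inputs: dict[str, float] = field(default_factory=dict)
    name: str = "model"

    def __post_init__(self):
        self.stoichiometry = np.asarray(self.stoichiometry, dtype=float)
        self.parameter_bounds = np.asarray(self.parameter_bounds, dtype=float)
        ns, nf = self.stoichiometry.shape
        if ns != len(self.state_names):
            raise ModelSpecError(
                f"stoichiometry has {ns} rows for {len(self.state_names)} states")
        if nf != len(self.fluxes):
            raise ModelSpecError(
                f"stoichiometry has {nf} columns for {len(self.fluxes)} fluxes")
        if self.parameter_bounds.shape != (len(self.parameter_names), 2):
            raise ModelSpecError("parameter_bounds must be (n_params, 2)")
        if np.any(self.parameter_bounds[:, 0] < 0):
            raise ModelSpecError("parameter lower bounds must be >= 0")
        if self.baseline_guess is not None:
            self.baseline_guess = np.asarray(self.baseline_guess, dtype=float)
        self._compile()

    # -- symbolic compilation -------------------------------------------------

    def _compile(self) -> None:
        syms = {n: sp.Symbol(n) for n in
                (*self.state_names, *self.parameter_names, *self.inputs)}
        syms["t"] = sp.Symbol("t")
        args = ([syms[n] for n in self.state_names]
                + [syms[n] for n in self.parameter_names]
                + [syms[n] for n in self.inputs] + [syms["t"]])

        def parse(expr: str, extra: dict | None = None) -> sp.Expr:
            local = dict(syms)
            if extra:
                local.update(extra)
            try:
                tree = sp.sympify(expr, locals=local)
            except (sp.SympifyError, SyntaxError) as exc:
                raise ModelSpecError(f"cannot parse expression {expr!r}: {exc}")
            free = tree.free_symbols - set(local.values())
            if free:
                raise ModelSpecError(
                    f"expression {expr!r} references unknown symbols "
                    f"{sorted(s.name for s in free)}")
            return tree

        flux_trees = [parse(_flux_expression(fx)) for fx in self.fluxes]
        flux_syms = {fx["name"]: tree
                     for fx, tree in zip(self.fluxes, flux_trees)}
        out_trees = [parse(o["expr"], extra=flux_syms) for o in self.outputs]

        self._flux_fn = sp.lambdify(args, sp.Matrix(flux_trees), "numpy")
        self._out_fn = sp.lambdify(args, sp.Matrix(out_trees), "numpy")
        if self.initial_states is not None:
            if len(self.initial_states) != len(self.state_names):
                raise ModelSpecError("initial_states length mismatch")
            p_args = [syms[n] for n in self.parameter_names]
            trees = [parse(e) for e in self.initial_states]
            bad = [str(t) for t in trees
                   if t.free_symbols - set(p_args)]
            if bad:
                raise ModelSpecError(
                    f"initial_states must depend on parameters only: {bad}")
            self._x0_fn = sp.lambdify(p_args, sp.Matrix(trees), "numpy")
        else:
            self._x0_fn = None

    # -- convenience ----------------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    @property
    def n_fluxes(self) -> int:
        return len(self.fluxes)

    @property
    def flux_names(self) -> list[str]:
        return [fx["name"] for fx in self.fluxes]

    @property
    def output_names(self) -> list[str]:
        return [o["name"] for o in self.outputs]

    def _call_args(self, x: np.ndarray, p: np.ndarray, t: float) -> list:
        return [*x, *p, *self.inputs.values(), t]

    def flux_values(self, x: np.ndarray, p: np.ndarray, t: float = 0.0) -> np.ndarray:
        """Evaluate all flux laws at one state/parameter point."""
        return np.asarray(self._flux_fn(*self._call_args(x, p, t)),
                          dtype=float).ravel()

    def output_values(self, x: np.ndarray, p: np.ndarray, t: float = 0.0) -> np.ndarray:
        """Evaluate the output map g at one state/parameter point."""
        return np.asarray(self._out_fn(*self._call_args(x, p, t)),
                          dtype=float).ravel()

    def initial_state(self, p: np.ndarray) -> np.ndarray:
        """Evaluate x0(p); requires ``initial_states`` in the spec."""
        if self._x0_fn is None:
            raise ModelSpecError(f"model {self.name!r} declares no initial_states")
        return np.asarray(self._x0_fn(*np.asarray(p, float)), dtype=float).ravel()

    def rhs(self, t: float, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        """Time derivative N·f(x, p, u)."""
        return self.stoichiometry @ self.flux_values(x, p, t)

    # -- (de)serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "states": self.state_names,
            "parameters": [
                {"name": n, "bounds": [float(lo), float(hi)]}
                for n, (lo, hi) in zip(self.parameter_names, self.parameter_bounds)
            ],
            "stoichiometry": self.stoichiometry.astype(float).tolist(),
            "fluxes": self.fluxes,
            "outputs": self.outputs,
        }
        if self.baseline_guess is not None:
            for entry, g in zip(d["parameters"], self.baseline_guess):
                entry["guess"] = float(g)
        if self.initial_states is not None:
            d["initial_states"] = self.initial_states
        if self.inputs:
            d["inputs"] = self.inputs
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MetabolicModel":
        params = d["parameters"]
        guesses = [p.get("guess") for p in params]
        return cls(
            state_names=list(d["states"]),
            parameter_names=[p["name"] for p in params],
            stoichiometry=np.asarray(d["stoichiometry"], dtype=float),
            fluxes=list(d["fluxes"]),
            outputs=list(d["outputs"]),
            parameter_bounds=np.asarray([p["bounds"] for p in params], float),
            baseline_guess=(np.asarray(guesses, float)
                            if all(g is not None for g in guesses) else None),
            initial_states=d.get("initial_states"),
            inputs=dict(d.get("inputs", {})),
            name=d.get("name", "model"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MetabolicModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SimulationResult:
    """Trajectories returned by :func:`simulate`.

    All matrices are indexed time-major: ``states[k]`` is the state vector
    at ``time_grid[k]``.
    """

    time_grid: np.ndarray
    states: np.ndarray
    fluxes: np.ndarray
    outputs: np.ndarray
    diagnostics: list[str] = field(default_factory=list)


def _check_finite(t: float, x: np.ndarray, model: MetabolicModel) -> None:
    if not np.all(np.isfinite(x)):
        i = int(np.argmax(~np.isfinite(x)))
        raise IntegrationError(
            f"non-finite state {model.state_names[i]!r} at t={t:.6g}",
            time=t, state=model.state_names[i])


def simulate(model: MetabolicModel, x0: Sequence[float], p: Sequence[float],
             t_span: tuple[float, float], eval_times: Sequence[float],
             *, rtol: float = 1e-6, atol: float = 1e-6,
             method: str = "LSODA") -> SimulationResult:
    """Integrate dx/dt = N f(x, p, u) and evaluate fluxes and outputs.

    Parameters are held constant over ``t_span``.  ``eval_times`` must lie
    inside ``t_span``.  States are not clipped; dips below -1e-8 are
    reported in ``diagnostics`` rather than silently corrected.
    """
    x0 = np.asarray(x0, dtype=float)
    p = np.asarray(p, dtype=float)
    eval_times = np.asarray(eval_times, dtype=float)
    if x0.shape != (model.n_states,):
        raise ValueError(f"x0 must have length {model.n_states}")
    if eval_times.size and (eval_times.min() < t_span[0] - 1e-12
                            or eval_times.max() > t_span[1] + 1e-12):
        raise ValueError("eval_times must lie within t_span")
    if np.any(np.diff(eval_times) <= 0):
        raise ValueError("eval_times must be strictly increasing")

    def guarded_rhs(t, x, p):
        # fail fast: stiff solvers can grind indefinitely once the state
        # or derivative leaves the finite range
        if not np.all(np.isfinite(x)) or np.any(np.abs(x) > 1e100):
            bad = int(np.argmax(~np.isfinite(x) | (np.abs(x) > 1e100)))
            raise IntegrationError(
                f"state {model.state_names[bad]!r} diverged at t={t:.6g}",
                time=float(t), state=model.state_names[bad])
        dx = model.rhs(t, x, p)
        if not np.all(np.isfinite(dx)):
            bad = int(np.argmax(~np.isfinite(dx)))
            raise IntegrationError(
                f"non-finite derivative of state {model.state_names[bad]!r} "
                f"at t={t:.6g}", time=float(t), state=model.state_names[bad])
        return dx

    sol = solve_ivp(guarded_rhs, t_span, x0, t_eval=eval_times, args=(p,),
                    method=method, rtol=rtol, atol=atol)
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else t_span[0]
        x_last = sol.y[:, -1] if sol.t.size else x0
        deriv = model.rhs(t_fail, x_last, p)
        bad = int(np.argmax(~np.isfinite(deriv))) if not np.all(
            np.isfinite(deriv)) else int(np.argmax(np.abs(deriv)))
        raise IntegrationError(
            f"integration failed at t={t_fail:.6g} "
            f"(state {model.state_names[bad]!r}): {sol.message}",
            time=float(t_fail), state=model.state_names[bad])

    states = sol.y.T
    for k, t in enumerate(eval_times):
        _check_finite(t, states[k], model)

    fluxes = np.empty((eval_times.size, model.n_fluxes))
    outputs = np.empty((eval_times.size, len(model.outputs)))
    for k, t in enumerate(eval_times):
        fluxes[k] = model.flux_values(states[k], p, t)
        outputs[k] = model.output_values(states[k], p, t)

    diagnostics = []
    low = states.min(axis=0)
    for i, v in enumerate(low):
        if v < NEGATIVE_STATE_FLOOR:
            diagnostics.append(
                f"state {model.state_names[i]!r} reached {v:.3g} < "
                f"{NEGATIVE_STATE_FLOOR:g}")
    return SimulationResult(eval_times, states, fluxes, outputs, diagnostics)


def simulate_segment(model: MetabolicModel, x_prev: Sequence[float],
                     p_n: Sequence[float], t_start: float, dt: float,
                     *, rtol: float = 1e-6, atol: float = 1e-6,
                     method: str = "LSODA"
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance the system one segment of length ``dt`` under fixed p_n.

    Returns the end state, the output vector and the flux vector at the
    segment end node, realizing the chained per-segment discretization
    (the end state of segment n-1 seeds segment n).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t_end = t_start + dt
    res = simulate(model, x_prev, p_n, (t_start, t_end), [t_end],
                   rtol=rtol, atol=atol, method=method)
    return res.states[0], res.outputs[0], res.fluxes[0]
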