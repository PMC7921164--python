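"""Longitudinal mean±SD datasets and Monte Carlo spline ensembles.

Measurements arrive as per-observable means and standard deviations at a
handful of time points (days).  A continuous stand-in for each observable
is built by (i) drawing a Gaussian realization of every data point,
(ii) fitting a cubic smoothing spline through the realization, and
(iii) repeating, which yields an ensemble of interpolants whose pointwise
spread propagates the measurement uncertainty into everything downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline

__all__ = [
    "LongitudinalDataset",
    "Curve",
    "SplineEnsemble",
    "sample_realization",
    "fit_spline",
    "build_ensemble",
    "central_band",
    "sd_floor",
]

#: minimum anchors for a full cubic smoothing spline (scipy requirement)
_MIN_CUBIC = 5


def sd_floor(means: np.ndarray) -> np.ndarray:
    """Floor for standard deviations / weight denominators.

    eps = 1e-6·|mean| + 1e-12 keeps (1/sd)^2 weights finite for sd = 0.
    """
    return 1e-6 * np.abs(means) + 1e-12


@dataclass
class LongitudinalDataset:
    """Per-observable means and SDs on a shared time grid.

    ``means``/``sds`` have shape (n_observables, n_times); missing
    observations are NaN in ``means`` and are skipped everywhere (the
    baseline-only measurement pattern).  ``kinds`` flags each observable
    as ``"metabolic"`` or ``"transcript"``.
    """

    observables: list[str]
    times: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    kinds: list[str] = field(default_factory=list)
    counts: np.ndarray | None = None
    nonnegative: bool = True

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        shape = (len(self.observables), self.times.size)
        if self.means.shape != shape or self.sds.shape != shape:
            raise ValueError(f"means/sds must have shape {shape}")
        if np.any(self.sds[np.isfinite(self.sds)] < 0):
            raise ValueError("sds must be nonnegative")
        if not self.kinds:
            self.kinds = ["metabolic"] * len(self.observables)
        if len(self.kinds) != len(self.observables):
            raise ValueError("one kind per observable required")

    # -- accessors ------------------------------------------------------------

    def index(self, observable: str) -> int:
        try:
            return self.observables.index(observable)
        except ValueError:
            raise KeyError(f"unknown observable {observable!r}") from None

    def available_mask(self, observable: str) -> np.ndarray:
        return np.isfinite(self.means[self.index(observable)])

    def sd_function(self, observable: str) -> "SdInterpolant":
        """Linear-in-time interpolant of the floored SDs of one observable."""
        i = self.index(observable)
        mask = self.available_mask(observable)
        t, m, s = self.times[mask], self.means[i, mask], self.sds[i, mask]
        return SdInterpolant(t, np.maximum(s, sd_floor(m)))

    def subset(self, kind: str) -> "LongitudinalDataset":
        idx = [i for i, k in enumerate(self.kinds) if k == kind]
        return LongitudinalDataset(
            observables=[self.observables[i] for i in idx],
            times=self.times.copy(),
            means=self.means[idx].copy(),
            sds=self.sds[idx].copy(),
            kinds=[kind] * len(idx),
            counts=None if self.counts is None else self.counts[idx].copy(),
            nonnegative=self.nonnegative,
        )

    # -- I/O (long-format CSV: observable, kind, time, mean, sd, n) ----------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, obs in enumerate(self.observables):
            for j, t in enumerate(self.times):
                if not np.isfinite(self.means[i, j]):
                    continue
                rows.append({
                    "observable": obs, "kind": self.kinds[i], "time": t,
                    "mean": self.means[i, j], "sd": self.sds[i, j],
                    "n": (int(self.counts[i, j])
                          if self.counts is not None else ""),
                })
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LongitudinalDataset":
        required = {"observable", "kind", "time", "mean", "sd"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        times = np.unique(df["time"].to_numpy(dtype=float))
        observables = list(dict.fromkeys(df["observable"]))
        kinds, have_n = [], "n" in df.columns and df["n"].notna().all()
        means = np.full((len(observables), times.size), np.nan)
        sds = np.full_like(means, np.nan)
        counts = np.zeros(means.shape, dtype=int) if have_n else None
        for i, obs in enumerate(observables):
            sub = df[df["observable"] == obs].sort_values("time")
            if sub["time"].duplicated().any():
                raise ValueError(f"duplicate times for observable {obs!r}")
            kinds.append(str(sub["kind"].iloc[0]))
            j = np.searchsorted(times, sub["time"].to_numpy(dtype=float))
            means[i, j] = sub["mean"].to_numpy(dtype=float)
            sds[i, j] = sub["sd"].to_numpy(dtype=float)
            if have_n:
                counts[i, j] = sub["n"].to_numpy(dtype=int)
        return cls(observables, times, means, sds, kinds, counts)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LongitudinalDataset":
        # round_trip parsing keeps write -> read -> write byte-identical
        return cls.from_frame(pd.read_csv(path,
                                          float_precision="round_trip"))


class SdInterpolant:
    """Picklable linear-in-time SD interpolant (constant outside the data)."""

    def __init__(self, times: np.ndarray, sds: np.ndarray):
        self.times = np.asarray(times, dtype=float)
        self.sds = np.asarray(sds, dtype=float)

    def __call__(self, t):
        return np.interp(t, self.times, self.sds)


class Curve:
    """A piecewise-polynomial interpolant restricted to its fit domain.

    Evaluation outside [t_first, t_last] raises ``ValueError`` — the
    trajectory machinery never extrapolates.
    """

    def __init__(self, poly, domain: tuple[float, float],
                 anchors: tuple[np.ndarray, np.ndarray] | None = None):
        self._poly = poly
        self.domain = (float(domain[0]), float(domain[1]))
        self.anchors = anchors

    def _check(self, t):
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
            raise ValueError(
                f"evaluation outside spline domain [{lo:g}, {hi:g}]")
        return np.clip(t, lo, hi)

    def __call__(self, t):
        out = self._poly(self._check(t))
        return float(out) if np.isscalar(t) else np.asarray(out, float)

    def derivative(self, t):
        if hasattr(self._poly, "derivative"):
            dp = self._poly.derivative()
        else:  # numpy Polynomial fallback for degraded fits
            dp = self._poly.deriv()
        out = dp(self._check(t))
        return float(out) if np.isscalar(t) else np.asarray(out, float)


def sample_realization(data: LongitudinalDataset,
                       rng: np.random.Generator | int) -> np.ndarray:
    """Draw one Gaussian realization of every (observable, time) value.

    Values are drawn independently Normal(mean, sd); for nonnegative
    datasets the draws are truncated at 0.  Missing entries stay NaN.
    """
    rng = np.random.default_rng(rng)
    draws = rng.normal(data.means, data.sds)
    if data.nonnegative:
        draws = np.maximum(draws, 0.0)
    draws[~np.isfinite(data.means)] = np.nan
    return draws


def fit_spline(times: Sequence[float], values: Sequence[float],
               sds: Sequence[float] | None = None,
               smoothing: float = 1.0) -> Curve:
    """Fit a cubic smoothing spline through anchor points.

    The spline minimizes ``q·Σ w_i (v_i − s(t_i))² + (1−q)·∫ s''²`` with
    weights ``w_i = 1/sd_i²`` (floored) and smoothing level ``q``
    (``smoothing``).  ``q = 1`` interpolates the anchors exactly with a
    natural cubic spline.  Fewer than 5 anchors degrade to an
    interpolating polynomial with a warning.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size:
        raise ValueError("times and values must have equal length")
    if t.size < 2:
        raise ValueError("need at least 2 anchor points")
    if np.unique(t).size != t.size:
        raise ValueError("duplicate anchor times")
    order = np.argsort(t)
    t, v = t[order], v[order]
    if not 0 < smoothing <= 1:
        raise ValueError("smoothing level must lie in (0, 1]")

    if smoothing == 1.0:
        if t.size >= 3:
            poly = CubicSpline(t, v, bc_type="natural")
        else:
            warnings.warn("2 anchors: degraded to linear interpolant")
            poly = np.polynomial.Polynomial.fit(t, v, deg=1)
        return Curve(poly, (t[0], t[-1]), anchors=(t, v))

    if t.size < _MIN_CUBIC:
        warnings.warn(
            f"{t.size} anchors < {_MIN_CUBIC}: smoothing disabled, degraded "
            "to interpolating polynomial")
        poly = np.polynomial.Polynomial.fit(t, v, deg=t.size - 1)
        return Curve(poly, (t[0], t[-1]), anchors=(t, v))

    if sds is None:
        w = np.ones_like(v)
    else:
        s = np.asarray(sds, dtype=float)[order]
        w = 1.0 / np.maximum(s, sd_floor(v)) ** 2
    lam = (1.0 - smoothing) / smoothing
    poly = make_smoothing_spline(t, v, w=w, lam=lam)
    return Curve(poly, (t[0], t[-1]), anchors=(t, v))


@dataclass
class SplineEnsemble:
    """Monte Carlo collection of per-observable splines.

    ``splines[s][obs]`` is the spline of observable ``obs`` in sample
    ``s``; ``anchors[s]`` stores the sampled matrix that produced it.
    Observables with fewer than 2 available time points (baseline-only
    measurements) carry no spline and are used in baseline calibration
    only.
    """

    splines: list[dict[str, Curve]]
    anchors: list[np.ndarray]
    sample_seed: int
    source: LongitudinalDataset

    @property
    def n_samples(self) -> int:
        return len(self.splines)

    def observables(self) -> list[str]:
        return list(self.splines[0].keys()) if self.splines else []


def build_ensemble(data: LongitudinalDataset, n_samples: int,
                   rng_seed: int, smoothing: float = 1.0) -> SplineEnsemble:
    """Build the Monte Carlo spline ensemble for a dataset.

    Each sample draws an independent Gaussian realization of the data and
    fits one smoothing spline per observable through it.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ss = np.random.SeedSequence(rng_seed)
    splines, anchors = [], []
    for s, child in enumerate(ss.spawn(n_samples)):
        rng = np.random.default_rng(child)
        drawn = sample_realization(data, rng)
        per_obs: dict[str, Curve] = {}
        for i, obs in enumerate(data.observables):
            mask = np.isfinite(drawn[i])
            if mask.sum() < 2:
                continue  # baseline-only observable: no continuous stand-in
            try:
                per_obs[obs] = fit_spline(
                    data.times[mask], drawn[i, mask],
                    sds=data.sds[i, mask], smoothing=smoothing)
            except ValueError as exc:
                raise ValueError(
                    f"spline fit failed for {obs!r} in sample {s}: {exc}"
                ) from exc
        splines.append(per_obs)
        anchors.append(drawn)
    return SplineEnsemble(splines, anchors, int(rng_seed), data)


def central_band(ensemble: SplineEnsemble, observable: str, fraction: float,
                 eval_times: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise central-``fraction`` envelope across ensemble members."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    eval_times = np.asarray(eval_times, dtype=float)
    vals = np.array([s[observable](eval_times) for s in ensemble.splines])
    alpha = (1.0 - fraction) / 2.0
    lower = np.quantile(vals, alpha, axis=0)
    upper = np.quantile(vals, 1.0 - alpha, axis=0)
    return lower, upper
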