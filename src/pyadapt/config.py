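"""Run configuration: one YAML file describing a reproducible run.

Defaults mirror the estimator's standard operating point (200 segments,
2×10^5 scatter draws keeping 10%, integration tolerances 1e-6, optimizer
termination 1e-10); every run archives its effective configuration so
results are self-describing.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .estimation import SolverSettings

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration; ``violations`` lists every problem."""

    def __init__(self, violations: list[str]):
        super().__init__("invalid configuration:\n  - "
                         + "\n  - ".join(violations))
        self.violations = violations


@dataclass
class RunConfig:
    """Everything a run needs, with file paths and numerical settings."""

    # input files
    model_file: str = "model.json"
    metabolic_file: str = "metabolic.csv"
    transcript_file: str = "transcript.csv"
    coupling_file: str = "coupling.csv"
    output_dir: str = "run_output"

    # discretization
    n_segments: int = 200
    t_end: float = 21.0

    # baseline scatter search
    n_scatter: int = 200_000
    keep_fraction: float = 0.1
    scatter_low: float = 1e-6
    scatter_high: float = 1e6

    # spline ensemble
    n_spline_samples: int = 100
    spline_smoothing: float = 1.0

    # regularization: a fixed pair for `fit`, ranges for `scan`
    lambda_g1: float = 0.0
    lambda_g2: float = 0.0
    scan_runs: int = 200
    scan_zero_runs: int = 40
    lambda_g1_range: tuple[float, float] = (1e-4, 2.0)
    lambda_g2_range: tuple[float, float] = (1e-12, 1e-4)
    group_fraction: float = 0.05

    # solver settings
    rtol: float = 1e-6
    atol: float = 1e-6
    ode_method: str = "LSODA"
    ftol: float = 1e-10
    xtol: float = 1e-10
    gtol: float = 1e-10
    max_iterations: int = 1000
    max_evaluations: int = 100_000
    eq12_literal: bool = False
    collocation_points: int = 1

    seed: int = 0
    n_jobs: int = 1

    def solver_settings(self) -> SolverSettings:
        return SolverSettings(
            rtol=self.rtol, atol=self.atol, ode_method=self.ode_method,
            ftol=self.ftol, xtol=self.xtol, gtol=self.gtol,
            max_iterations=self.max_iterations,
            max_evaluations=self.max_evaluations,
            eq12_literal=self.eq12_literal,
            collocation_points=self.collocation_points)

    def validate(self, check_files: bool = False) -> None:
        """Raise :class:`ConfigError` listing every violation, not just one."""
        v: list[str] = []
        positive = ["n_segments", "t_end", "n_scatter", "n_spline_samples",
                    "scan_runs", "rtol", "atol", "ftol", "xtol", "gtol",
                    "max_iterations", "max_evaluations"]
        for name in positive:
            if getattr(self, name) <= 0:
                v.append(f"{name} must be positive (got {getattr(self, name)})")
        for name in ("keep_fraction", "group_fraction", "spline_smoothing"):
            if not 0 < getattr(self, name) <= 1:
                v.append(f"{name} must lie in (0, 1] "
                         f"(got {getattr(self, name)})")
        if self.lambda_g1 < 0 or self.lambda_g2 < 0:
            v.append("regularization constants must be nonnegative")
        if self.scan_zero_runs < 0 or self.scan_zero_runs > self.scan_runs:
            v.append("scan_zero_runs must lie in [0, scan_runs]")
        for rng_name in ("lambda_g1_range", "lambda_g2_range"):
            lo, hi = getattr(self, rng_name)
            if not 0 < lo <= hi:
                v.append(f"{rng_name} must satisfy 0 < low <= high")
        if not 0 < self.scatter_low <= self.scatter_high:
            v.append("scatter range must satisfy 0 < low <= high")
        if self.n_jobs == 0:
            v.append("n_jobs must be nonzero (-1 means all cores)")
        if self.collocation_points < 1:
            v.append("collocation_points must be >= 1")
        if check_files:
            for name in ("model_file", "metabolic_file", "transcript_file",
                         "coupling_file"):
                path = Path(getattr(self, name))
                if not path.is_file():
                    v.append(f"{name}: no such file {path}")
        if v:
            raise ConfigError(v)

    # -- YAML round-trip -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lambda_g1_range"] = list(d["lambda_g1_range"])
        d["lambda_g2_range"] = list(d["lambda_g2_range"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError([f"unknown config key {k!r}"
                               for k in sorted(unknown)])
        d = dict(d)
        for key in ("lambda_g1_range", "lambda_g2_range"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
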