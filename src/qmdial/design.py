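"""Experiment planning: K_D sweeps and resolvable-affinity windows.

Before running a dialysis binding assay it pays to simulate the chamber
concentrations over the affinity range of interest: as K_D grows the red and
white concentrations converge and the partition ratio decays towards the
control value, so at some point the assay can no longer distinguish
neighbouring K_D values given a stated measurement error.  ``kd_sweep``
produces the concentration/ratio curves; ``resolvable_kd_max`` formalises
the planning question as the largest K_D whose endpoint confidence interval
(white-chamber route) stays narrower than a chosen upper/lower ratio.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .equilibrium import ExperimentConfig, solve_equilibrium
from .errors import QmdialError, ValidationError
from .uncertainty import kd_interval_endpoints

__all__ = [
    "SweepResult",
    "ResolvabilityReport",
    "kd_sweep",
    "resolvable_kd_max",
    "export_curves",
    "read_curves",
]

_CONFIG_FIELDS = ("red_volume", "white_volume", "l0", "t0", "pc")


@dataclass(frozen=True)
class SweepResult:
    """Forward-solved concentration and partition-ratio curves over a K_D grid."""

    kd_grid: np.ndarray
    lwhite_series: np.ndarray
    lred_series: np.ndarray
    pt_series: np.ndarray
    config: ExperimentConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kd": self.kd_grid,
                "lwhite": self.lwhite_series,
                "lred": self.lred_series,
                "pt": self.pt_series,
            }
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SweepResult):
            return NotImplemented
        return self.config == other.config and all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in ("kd_grid", "lwhite_series", "lred_series", "pt_series")
        )


@dataclass(frozen=True)
class ResolvabilityReport:
    """Largest K_D resolvable under a stated measurement error, or None."""

    resolvable: bool
    kd_max: Optional[float]
    interval_at_max: Optional[tuple[float, float]]
    relative_half_width: float
    max_interval_ratio: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def kd_sweep(
    config: ExperimentConfig,
    kd_min: float = 0.0,
    kd_max: float = 500.0,
    n_points: int = 200,
    *,
    log: bool = False,
) -> SweepResult:
    """Forward-solve the equilibrium on an inclusive K_D grid.

    Linear grid by default (the natural axis for concentration-vs-K_D
    plots); ``log=True`` gives a log-spaced grid, which then requires
    ``kd_min > 0``.  ``kd_min = 0`` is evaluated by the stoichiometric
    branch of the solver.
    """
    if not (0 <= kd_min < kd_max):
        raise ValidationError("need 0 <= kd_min < kd_max")
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    if log:
        if kd_min <= 0:
            raise ValidationError("log grid requires kd_min > 0")
        grid = np.logspace(np.log10(kd_min), np.log10(kd_max), n_points)
    else:
        grid = np.linspace(kd_min, kd_max, n_points)
    states = [solve_equilibrium(config, kd) for kd in grid]
    return SweepResult(
        kd_grid=grid,
        lwhite_series=np.array([s.lwhite for s in states]),
        lred_series=np.array([s.lred for s in states]),
        pt_series=np.array([s.pt for s in states]),
        config=config,
    )


def resolvable_kd_max(
    config: ExperimentConfig,
    relative_half_width: float = 0.025,
    max_interval_ratio: float = 2.0,
    *,
    kd_min: float = 1.0,
    kd_max: float = 500.0,
    n_points: int = 200,
) -> ResolvabilityReport:
    """Largest K_D whose endpoint interval stays acceptably narrow.

    For each K_D on a log grid, the white-chamber concentration is
    forward-solved and the K_D interval from evaluating the estimator at
    lwhite·(1 ± half-width) is formed; the K_D passes when
    ``kd_upper / kd_lower <= max_interval_ratio``.  A K_D whose endpoints
    leave the estimator's valid domain counts as unresolvable.
    """
    if relative_half_width < 0:
        raise ValidationError("relative_half_width must be non-negative")
    if max_interval_ratio < 1:
        raise ValidationError("max_interval_ratio must be >= 1")
    grid = np.logspace(np.log10(kd_min), np.log10(kd_max), n_points)
    best_kd = None
    best_interval = None
    for kd in grid:
        lwhite = solve_equilibrium(config, kd).lwhite
        try:
            lo, hi = kd_interval_endpoints(config, lwhite, "lwhite", relative_half_width)
        except QmdialError:
            continue
        if lo > 0 and hi / lo <= max_interval_ratio:
            if best_kd is None or kd > best_kd:
                best_kd = float(kd)
                best_interval = (lo, hi)
    return ResolvabilityReport(
        resolvable=best_kd is not None,
        kd_max=best_kd,
        interval_at_max=best_interval,
        relative_half_width=relative_half_width,
        max_interval_ratio=max_interval_ratio,
    )


def export_curves(sweep: SweepResult, path, *, plot_path=None) -> None:
    """Write a sweep as CSV (kd, lwhite, lred, pt) with the configuration
    embedded as ``# key=value`` header comments; optionally render a plot."""
    if len(sweep.kd_grid) == 0:
        raise ValidationError("cannot export an empty sweep")
    with open(path, "w") as fh:
        for name in _CONFIG_FIELDS:
            fh.write(f"# {name}={getattr(sweep.config, name)!r}\n")
        sweep.to_frame().to_csv(fh, index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
        ax1.plot(sweep.kd_grid, sweep.lred_series, label="red chamber (total)")
        ax1.plot(sweep.kd_grid, sweep.lwhite_series, label="white chamber")
        ax1.set_ylabel("compound concentration (µM)")
        ax1.legend()
        ax2.plot(sweep.kd_grid, sweep.pt_series, color="k")
        ax2.set_xlabel("K$_D$ (µM)")
        ax2.set_ylabel("partition ratio p$_t$")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)


def read_curves(path) -> SweepResult:
    """Read a sweep CSV written by :func:`export_curves` back into a SweepResult."""
    cfg_kwargs = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            if key in _CONFIG_FIELDS:
                cfg_kwargs[key] = float(value)
    df = pd.read_csv(path, comment="#")
    return SweepResult(
        kd_grid=df["kd"].to_numpy(),
        lwhite_series=df["lwhite"].to_numpy(),
        lred_series=df["lred"].to_numpy(),
        pt_series=df["pt"].to_numpy(),
        config=ExperimentConfig(**cfg_kwargs),
    )
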