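"""1:1 protein–ligand equilibrium across a two-chamber equilibrium-dialysis device.

A rapid-equilibrium-dialysis (RED) insert has a small "red" chamber holding
the target protein and a larger "white" buffer reservoir, separated by a
membrane permeable only to the small molecule.  At equilibrium the compound
occupies three pools: free in the white chamber (``lwhite``), free in the red
chamber (``lfred``) and bound to protein in the red chamber (``tl``).  The
system is closed by

* mass conservation of ligand over both chambers,
* a control partition factor ``pc`` relating the free concentrations across
  the membrane (``lfred = pc * lwhite``; 1 for a perfectly equilibrating
  compound),
* protein conservation ``tf + tl = t0``, and
* the 1:1 binding law ``tl * KD = tf * lfred``.

Eliminating variables reduces the system to a single quadratic in the complex
concentration ``tl``; the physically admissible root (``0 <= tl <= t0``, all
concentrations non-negative) is selected by a cancellation-free formula.  The
three inverse estimators recover ``KD`` in closed form from any one of the
measurable quantities ``lwhite``, ``lred`` or the partition ratio
``pt = lred / lwhite``.

Units are fixed internally to µM (concentrations) and µL (volumes); callers
convert at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Tuple

from .errors import (
    InfeasibleMeasurementError,
    NoDetectableBindingError,
    ValidationError,
)

__all__ = [
    "ExperimentConfig",
    "EquilibriumState",
    "KdResult",
    "DEFAULT_KD_CEILING",
    "solve_equilibrium",
    "kd_from_pt",
    "kd_from_lwhite",
    "kd_from_lred",
    "check_physical",
]

#: Results above this K_D (µM) are flagged ``above_recommended_range`` but
#: still returned: the technique stays valid up to ~0.5 mM while precision
#: degrades well before that.
DEFAULT_KD_CEILING = 500.0

Observable = Literal["lwhite", "lred", "pt"]


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ExperimentConfig:
    """Geometry and composition of one quantitative-microdialysis run.

    Parameters
    ----------
    red_volume, white_volume
        Chamber volumes in µL (RED-device standard: 100 and 300).
    l0
        Ligand concentration in µM that both chambers would reach at
        equilibrium in the absence of protein (total ligand amount divided
        by total volume).
    t0
        Total target-protein concentration in the red chamber, µM.
    pc
        Control partition ratio (red/white concentration ratio in the
        protein-free control); 1.0 for an ideally equilibrating compound.
    """

    red_volume: float = 100.0
    white_volume: float = 300.0
    l0: float = 50.0
    t0: float = 80.0
    pc: float = 1.0

    def __post_init__(self):
        for name in ("red_volume", "white_volume", "l0", "t0", "pc"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))
        if self.red_volume <= 0 or self.white_volume <= 0:
            raise ValidationError("chamber volumes must be positive")
        if self.l0 <= 0:
            raise ValidationError("l0 must be positive")
        if self.t0 < 0:
            raise ValidationError("t0 must be non-negative")
        if self.pc <= 0:
            raise ValidationError("pc must be positive")

    @property
    def total_ligand(self) -> float:
        """Conserved ligand amount in µM·µL: l0 · (red_volume + white_volume)."""
        return self.l0 * (self.red_volume + self.white_volume)

    @property
    def _aw(self) -> float:
        """Effective white-side volume: white_volume + pc · red_volume."""
        return self.white_volume + self.pc * self.red_volume

    @property
    def lwhite_no_binding(self) -> float:
        """White-chamber concentration when no complex forms (µM)."""
        return self.total_ligand / self._aw

    @property
    def lred_no_binding(self) -> float:
        """Red-chamber concentration when no complex forms (µM)."""
        return self.pc * self.lwhite_no_binding


@dataclass(frozen=True)
class EquilibriumState:
    """All species concentrations (µM) at equilibrium, plus pt = lred/lwhite."""

    lwhite: float
    lfred: float
    tl: float
    tf: float
    lred: float
    pt: float


@dataclass(frozen=True)
class KdResult:
    """An estimated dissociation constant.

    ``method`` records which closed-form estimator produced it; ``std_error``
    and ``interval`` are filled by the uncertainty layer when replicate data
    or endpoint intervals are available.
    """

    kd: float
    method: Literal["from_pt", "from_lred", "from_lwhite"]
    std_error: Optional[float] = None
    interval: Optional[Tuple[float, float]] = None
    reliability_flag: Literal[
        "ok", "above_recommended_range", "no_detectable_binding"
    ] = "ok"

    def __post_init__(self):
        if self.reliability_flag != "no_detectable_binding" and not self.kd > 0:
            raise ValidationError("kd must be positive")
        if self.interval is not None:
            lo, hi = self.interval
            if not (lo <= self.kd <= hi):
                raise ValidationError("interval must bracket kd")


def _flag(kd: float, ceiling: float) -> str:
    return "above_recommended_range" if kd > ceiling else "ok"


def solve_equilibrium(config: ExperimentConfig, kd: float) -> EquilibriumState:
    """Forward-solve the equilibrium for a given dissociation constant.

    Parameters
    ----------
    config
        Experiment geometry and composition.
    kd
        Dissociation constant in µM, ``kd >= 0``.  ``kd = 0`` is handled by
        the stoichiometric-limit branch (binding to completion, bounded by
        whichever of protein or ligand is limiting).

    Returns
    -------
    EquilibriumState
        The unique physically admissible solution.
    """
    kd = _require_finite("kd", kd)
    if kd < 0:
        raise ValidationError("kd must be non-negative")

    R, W, pc, t0 = config.red_volume, config.white_volume, config.pc, config.t0
    L = config.total_ligand
    A = config._aw

    if t0 == 0:
        tl = 0.0
    elif kd == 0.0:
        # Stoichiometric limit: complex forms until protein or ligand runs out.
        tl = min(t0, L / R)
    else:
        # Quadratic in tl: pc·R·tl² − (pc·(t0·R + L) + kd·A)·tl + pc·t0·L = 0.
        # b < 0 always, so the smaller (admissible) root is 2c/(−b + √disc),
        # which is free of subtractive cancellation.
        a = pc * R
        b = -(pc * (t0 * R + L) + kd * A)
        c = pc * t0 * L
        disc = b * b - 4.0 * a * c
        tl = 2.0 * c / (-b + math.sqrt(max(disc, 0.0)))

    lwhite = (L - tl * R) / A
    lfred = pc * lwhite
    lred = lfred + tl
    tf = t0 - tl
    pt = lred / lwhite if lwhite > 0 else math.inf
    return EquilibriumState(lwhite=lwhite, lfred=lfred, tl=tl, tf=tf, lred=lred, pt=pt)


def _kd_from_w_tl(config: ExperimentConfig, w: float, tl: float) -> float:
    """K_D = tf·lfred/tl with tf = t0 − tl and lfred = pc·w."""
    return config.pc * w * (config.t0 - tl) / tl


def kd_from_pt(
    config: ExperimentConfig, pt: float, *, kd_ceiling: float = DEFAULT_KD_CEILING
) -> KdResult:
    """Estimate K_D from the measured partition ratio pt = lred/lwhite.

    Requires ``pt > pc``: binding enriches the red chamber beyond the
    control ratio.  ``pt <= pc`` means no detectable binding; a pt implying
    more complex than protein is infeasible.
    """
    pt = _require_finite("pt", pt)
    if pt <= 0:
        raise ValidationError("pt must be positive")
    if pt <= config.pc:
        raise NoDetectableBindingError(
            f"pt={pt:g} does not exceed the control ratio pc={config.pc:g}; "
            "K_D is undefined (no detectable binding)"
        )
    w = config.total_ligand / (config.white_volume + pt * config.red_volume)
    tl = (pt - config.pc) * w
    if tl >= config.t0:
        raise InfeasibleMeasurementError(
            f"pt={pt:g} implies complex {tl:g} µM >= total protein {config.t0:g} µM"
        )
    kd = _kd_from_w_tl(config, w, tl)
    return KdResult(kd=kd, method="from_pt", reliability_flag=_flag(kd, kd_ceiling))


def kd_from_lwhite(
    config: ExperimentConfig, lwhite: float, *, kd_ceiling: float = DEFAULT_KD_CEILING
) -> KdResult:
    """Estimate K_D from the white-chamber (protein-free side) concentration.

    Valid strictly between the stoichiometric floor (all protein occupied)
    and the no-binding concentration l0·(redvol+whitevol)/(whitevol+pc·redvol).
    """
    lwhite = _require_finite("lwhite", lwhite)
    if lwhite <= 0:
        raise ValidationError("lwhite must be positive")
    if lwhite >= config.lwhite_no_binding:
        raise NoDetectableBindingError(
            f"lwhite={lwhite:g} µM is at/above the protein-free equilibrium "
            f"concentration {config.lwhite_no_binding:g} µM"
        )
    tl = (config.total_ligand - lwhite * config._aw) / config.red_volume
    if tl >= config.t0:
        raise InfeasibleMeasurementError(
            f"lwhite={lwhite:g} µM implies complex {tl:g} µM >= total protein "
            f"{config.t0:g} µM (below the stoichiometric floor)"
        )
    kd = _kd_from_w_tl(config, lwhite, tl)
    return KdResult(kd=kd, method="from_lwhite", reliability_flag=_flag(kd, kd_ceiling))


def kd_from_lred(
    config: ExperimentConfig, lred: float, *, kd_ceiling: float = DEFAULT_KD_CEILING
) -> KdResult:
    """Estimate K_D from the total red-chamber concentration (free + bound)."""
    lred = _require_finite("lred", lred)
    if lred <= 0:
        raise ValidationError("lred must be positive")
    if lred <= config.lred_no_binding:
        raise NoDetectableBindingError(
            f"lred={lred:g} µM shows no enrichment over the control level "
            f"{config.lred_no_binding:g} µM"
        )
    w = (config.total_ligand - lred * config.red_volume) / config.white_volume
    if w <= 0:
        raise InfeasibleMeasurementError(
            f"lred={lred:g} µM exceeds the total-ligand budget "
            f"{config.total_ligand / config.red_volume:g} µM"
        )
    tl = lred - config.pc * w
    if tl >= config.t0:
        raise InfeasibleMeasurementError(
            f"lred={lred:g} µM implies complex {tl:g} µM >= total protein "
            f"{config.t0:g} µM"
        )
    kd = _kd_from_w_tl(config, w, tl)
    return KdResult(kd=kd, method="from_lred", reliability_flag=_flag(kd, kd_ceiling))


def check_physical(
    config: ExperimentConfig,
    state: EquilibriumState,
    kd: float,
    rtol: float = 1e-8,
) -> list[str]:
    """Report every equilibrium invariant the state violates.

    Residuals are scaled by the magnitude of the terms involved, so the
    empty list means all invariants hold to relative tolerance ``rtol``.
    """
    violations: list[str] = []

    def rel(residual: float, scale: float) -> float:
        return abs(residual) / max(abs(scale), 1.0)

    for name in ("lwhite", "lfred", "tl", "tf", "lred"):
        if getattr(state, name) < 0:
            violations.append(f"{name} < 0")
    if rel(state.lfred - config.pc * state.lwhite, state.lfred) > rtol:
        violations.append("lfred=pc*lwhite violated")
    if rel(state.lred - (state.lfred + state.tl), state.lred) > rtol:
        violations.append("lred=lfred+tl violated")
    if rel(state.tf + state.tl - config.t0, config.t0) > rtol:
        violations.append("tf+tl=t0 violated")
    if rel(state.tl * kd - state.tf * state.lfred, state.tl * kd) > rtol:
        violations.append("tl*KD=tf*lfred violated")
    total = state.lwhite * config.white_volume + state.lred * config.red_volume
    if rel(total - config.total_ligand, config.total_ligand) > rtol:
        violations.append("ligand conservation violated")
    return violations
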