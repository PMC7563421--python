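"""Synthetic calibration tables and dialysis experiments with known truth.

Emulates the measurement process of the dialysis workflow: true chamber
concentrations come from the forward equilibrium solve (target condition) or
from the pc-split control partition (control condition); the detector turns
each concentration into a peak area through the linear response
``area = k·conc + d`` corrupted by multiplicative log-normal noise with a
given coefficient of variation (chromatographic peak-area noise scales with
signal).  One noise model serves both HPLC and LC–MS modes — the mode only
changes concentration units (µM vs nM) and the 20× aliquot dilution.

Not emulated: retention-time drift, carry-over, co-elution, detector
saturation.  Recovery of the true K_D from these tables therefore tests the
numerical pipeline, not chromatographic robustness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import curve_from_frame, area_to_concentration
from .equilibrium import ExperimentConfig, solve_equilibrium
from .errors import ValidationError
from .uncertainty import Measurement, aggregate_replicates, propagate_kd_error
from .equilibrium import KdResult

__all__ = ["SyntheticSpec", "generate_experiment", "write_experiment", "recover_kd"]

#: Default calibration dilution series (µM) for the HPLC workflow.
HPLC_CAL_CONCENTRATIONS = (10.0, 25.0, 50.0, 75.0, 100.0)
#: Default calibration dilution series (nM) for the LC–MS workflow.
LCMS_CAL_CONCENTRATIONS = (50.0, 100.0, 500.0, 1000.0, 1500.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Everything needed to generate one synthetic dialysis experiment.

    The default configuration is the standard HPLC system: 100/300 µL
    chambers, protein at 80 µM, ligand equilibrating to 50 µM, pc = 1.
    """

    config: ExperimentConfig = field(default_factory=ExperimentConfig)
    true_kd: float = 100.0
    noise_cv: float = 0.02
    n_replicates: int = 3
    calibration_k: float = 153.2
    calibration_d: float = 40.1
    seed: int = 0
    mode: str = "HPLC"
    compound_id: str = "compound_1"

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be non-negative")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.true_kd < 0:
            raise ValidationError("true_kd must be non-negative")
        if self.mode not in ("HPLC", "LCMS"):
            raise ValidationError("mode must be 'HPLC' or 'LCMS'")

    @property
    def dilution_factor(self) -> float:
        return 20.0 if self.mode == "LCMS" else 1.0

    @property
    def unit_scale(self) -> float:
        """µM → curve units (nM for LC–MS)."""
        return 1000.0 if self.mode == "LCMS" else 1.0


def _noisy_area(rng: np.random.Generator, true_area: float, cv: float) -> float:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return true_area
    s = math.sqrt(math.log1p(cv * cv))
    return true_area * math.exp(rng.normal(-0.5 * s * s, s))


def generate_experiment(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (calibration table, sample table) for one experiment.

    The sample table holds ``n_replicates`` devices for the control
    condition (no protein, pc-split concentrations) and the same number for
    the target condition (concentrations from the forward solve at
    ``true_kd``).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cfg = spec.config

    cal_concs = HPLC_CAL_CONCENTRATIONS if spec.mode == "HPLC" else LCMS_CAL_CONCENTRATIONS
    cal_rows = []
    for conc in cal_concs:
        for rep in range(1, 4):
            area = _noisy_area(rng, spec.calibration_k * conc + spec.calibration_d, spec.noise_cv)
            cal_rows.append(
                {
                    "compound_id": spec.compound_id,
                    "concentration_uM": conc,
                    "peak_area": area,
                    "replicate": rep,
                }
            )
    cal_df = pd.DataFrame(cal_rows)

    # True chamber concentrations (µM) for each condition.
    control_white = cfg.lwhite_no_binding
    control_red = cfg.pc * control_white
    target = solve_equilibrium(cfg, spec.true_kd)

    sample_rows = []
    for condition, red_conc, white_conc in (
        ("control", control_red, control_white),
        ("target", target.lred, target.lwhite),
    ):
        for rep in range(1, spec.n_replicates + 1):
            for chamber, conc in (("red", red_conc), ("white", white_conc)):
                measured = conc * spec.unit_scale / spec.dilution_factor
                area = _noisy_area(
                    rng, spec.calibration_k * measured + spec.calibration_d, spec.noise_cv
                )
                sample_rows.append(
                    {
                        "compound_id": spec.compound_id,
                        "sample_id": f"{condition}_{rep}",
                        "chamber": chamber,
                        "condition": condition,
                        "peak_area": area,
                        "retention_time_min": 12.5,
                        "dilution_factor": spec.dilution_factor,
                    }
                )
    samples_df = pd.DataFrame(sample_rows)
    return cal_df, samples_df


def write_experiment(spec: SyntheticSpec, outdir) -> tuple[Path, Path]:
    """Write the generated tables as CSV files; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cal_df, samples_df = generate_experiment(spec)
    cal_path = outdir / f"{spec.compound_id}_calibration.csv"
    samples_path = outdir / f"{spec.compound_id}_samples.csv"
    cal_df.to_csv(cal_path, index=False, float_format="%.10g")
    samples_df.to_csv(samples_path, index=False, float_format="%.10g")
    return cal_path, samples_path


def recover_kd(
    cal_df: pd.DataFrame,
    samples_df: pd.DataFrame,
    config: ExperimentConfig,
    *,
    mode: str = "HPLC",
) -> KdResult:
    """Full analysis pipeline: areas → concentrations → pc, pt → K_D ± σ.

    Fits the calibration curve, back-calculates each chamber concentration,
    forms per-device partition ratios for the control (pc) and target (pt)
    conditions, and propagates replicate scatter (of both pt and pc) into
    the K_D standard error via the pt-route estimator.  The measured pc
    replaces the configured value.
    """
    curve = curve_from_frame(cal_df, mode=mode)

    def ratios(condition: str) -> list[float]:
        rows = samples_df[samples_df["condition"] == condition]
        if rows.empty:
            raise ValidationError(f"no rows for condition {condition!r}")
        out = []
        for sid, grp in rows.groupby("sample_id"):
            conc = {}
            for chamber in ("red", "white"):
                sub = grp[grp["chamber"] == chamber]
                if sub.empty:
                    raise ValidationError(f"sample {sid!r} lacks a {chamber} row")
                conc[chamber] = np.mean(
                    [
                        area_to_concentration(curve, r.peak_area, r.dilution_factor)
                        for r in sub.itertuples()
                    ]
                )
            out.append(conc["red"] / conc["white"])
        return out

    pc_m = aggregate_replicates(ratios("control"))
    pt_m = aggregate_replicates(ratios("target"))
    return propagate_kd_error(config, pt_m, "pt", pc_measurement=pc_m)
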