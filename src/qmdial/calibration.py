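"""Detector calibration, partition-ratio QC and mass-balance bookkeeping.

Chromatographic (HPLC) or mass-spectrometric (LC–MS) peak areas are related
to concentration by a linear detector response ``area = k·conc + d`` fitted
from a dilution series run in triplicate.  This module fits that curve,
back-calculates sample concentrations (with the LC–MS 20× aliquot dilution
folded in), forms the control partition ratio p_c, checks compound recovery
against the introduced amount, and applies the exclusion rules: a compound
is dropped when p_c leaves [0.90, 1.10] (poor equilibration, surface binding
or aggregation) or when more than 10% of the input amount is unaccounted for
(adhesion, precipitation).

CSV schemas
-----------
Calibration table: ``compound_id, concentration_uM, peak_area, replicate``.
Sample table: ``compound_id, sample_id, chamber{red|white},
condition{control|target|control_protein}, peak_area, retention_time_min,
dilution_factor``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BelowBlankError, CalibrationError, ValidationError

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "PeakRecord",
    "QcReport",
    "PC_RANGE",
    "RECOVERY_TOLERANCE",
    "fit_calibration",
    "area_to_concentration",
    "compute_pc",
    "mass_balance",
    "lred_from_total",
    "read_calibration_csv",
    "read_samples_csv",
    "evaluate_qc",
]

#: Acceptable control partition ratio band: outside it the compound did not
#: equilibrate cleanly and is considered for exclusion.
PC_RANGE = (0.90, 1.10)
#: Acceptable deviation of mass recovery from 1.0.
RECOVERY_TOLERANCE = 0.10

CALIBRATION_COLUMNS = ["compound_id", "concentration_uM", "peak_area", "replicate"]
SAMPLE_COLUMNS = [
    "compound_id",
    "sample_id",
    "chamber",
    "condition",
    "peak_area",
    "retention_time_min",
    "dilution_factor",
]


@dataclass(frozen=True)
class CalibrationPoint:
    concentration: float  # curve units: µM in HPLC mode, nM in LC–MS mode
    peak_area: float
    replicate_id: int = 0

    def __post_init__(self):
        if not self.concentration > 0:
            raise ValidationError("calibration concentration must be positive")
        if self.peak_area < 0:
            raise ValidationError("peak area must be non-negative")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear detector-response model area = k·concentration + d."""

    k: float
    d: float
    r_squared: float
    range_low: float
    range_high: float
    mode: Literal["HPLC", "LCMS"] = "HPLC"
    flagged_points: tuple = field(default=())

    def __post_init__(self):
        if not self.k > 0:
            raise ValidationError("calibration slope must be positive")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError("r_squared must lie in [0, 1]")
        if not self.range_low < self.range_high:
            raise ValidationError("range_low must be below range_high")

    def area_for(self, concentration: float) -> float:
        return self.k * concentration + self.d

    def in_range(self, concentration: float) -> bool:
        return self.range_low <= concentration <= self.range_high


@dataclass(frozen=True)
class PeakRecord:
    sample_id: str
    chamber: Literal["red", "white"]
    peak_area: float
    retention_time: float = float("nan")
    dilution_factor: float = 1.0

    def __post_init__(self):
        if self.peak_area < 0:
            raise ValidationError("peak area must be non-negative")
        if self.dilution_factor < 1:
            raise ValidationError("dilution_factor must be >= 1")
        if self.chamber not in ("red", "white"):
            raise ValidationError("chamber must be 'red' or 'white'")


@dataclass(frozen=True)
class QcReport:
    """Compound-only test verdict: equilibration and recovery classification."""

    pc: float
    pc_class: Literal["pass", "fail"]
    recovery: float
    recovery_class: Literal["pass", "fail"]
    excluded: bool
    reasons: tuple = ()

    def to_dict(self) -> dict:
        out = asdict(self)
        out["reasons"] = list(self.reasons)
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def fit_calibration(
    points: Sequence[CalibrationPoint],
    *,
    mode: str = "HPLC",
    r_squared_min: float = 0.99,
    residual_sigma_factor: float = 3.0,
) -> CalibrationCurve:
    """Ordinary least squares fit of peak area against concentration.

    Points whose residual exceeds ``residual_sigma_factor`` times the
    residual standard deviation are flagged (not dropped), as is the whole
    fit when r² falls below ``r_squared_min`` — a conservative linear-range
    diagnostic the caller may act on.
    """
    if len(points) < 2:
        raise CalibrationError("at least two calibration points are required")
    x = np.array([p.concentration for p in points], dtype=float)
    y = np.array([p.peak_area for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise CalibrationError("at least two distinct concentrations are required")

    fit = stats.linregress(x, y)
    if fit.slope <= 0:
        raise CalibrationError(
            f"fitted slope {fit.slope:g} is not positive: detector anomaly"
        )
    r2 = float(fit.rvalue**2)

    residuals = y - (fit.slope * x + fit.intercept)
    sigma = float(np.std(residuals))
    flagged = []
    if sigma > 0:
        for p, r in zip(points, residuals):
            if abs(r) > residual_sigma_factor * sigma:
                flagged.append(p)
    if r2 < r_squared_min:
        warnings.warn(
            f"calibration r²={r2:.4f} below {r_squared_min}: response may be "
            "outside the detector's linear range",
            stacklevel=2,
        )
    return CalibrationCurve(
        k=float(fit.slope),
        d=float(fit.intercept),
        r_squared=min(r2, 1.0),
        range_low=float(x.min()),
        range_high=float(x.max()),
        mode=mode,
        flagged_points=tuple(flagged),
    )


def area_to_concentration(
    curve: CalibrationCurve, area: float, dilution_factor: float = 1.0
) -> float:
    """Back-calculate the pre-dilution sample concentration from a peak area.

    ``concentration = dilution_factor · (area − d) / k``; a negative
    back-calculated value (area below the fitted blank) is an error rather
    than a clamp, to surface detector drift.
    """
    if area < 0:
        raise ValidationError("peak area must be non-negative")
    if dilution_factor < 1:
        raise ValidationError("dilution_factor must be >= 1")
    measured = (area - curve.d) / curve.k
    if measured < 0:
        raise BelowBlankError(
            f"area {area:g} is below the calibration intercept {curve.d:g}"
        )
    if not curve.in_range(measured):
        warnings.warn(
            f"back-calculated concentration {measured:g} lies outside the "
            f"validated linear range [{curve.range_low:g}, {curve.range_high:g}]",
            stacklevel=2,
        )
    return dilution_factor * measured


def compute_pc(red: PeakRecord, white: PeakRecord) -> tuple[float, str]:
    """Control partition ratio from dilution-corrected red/white peak areas.

    Detector linearity within the calibrated range means the area ratio
    equals the concentration ratio when both aliquots share the same
    calibration, so no curve is needed here.
    """
    if white.peak_area == 0:
        raise ValidationError("white-chamber peak area is zero; pc undefined")
    pc = (red.peak_area * red.dilution_factor) / (white.peak_area * white.dilution_factor)
    pc_class = "pass" if PC_RANGE[0] <= pc <= PC_RANGE[1] else "fail"
    return pc, pc_class


def mass_balance(
    conc_red: float,
    conc_white: float,
    red_volume: float,
    white_volume: float,
    input_amount_mol: float,
) -> tuple[float, str]:
    """Fraction of the introduced compound amount recovered across chambers.

    Concentrations in µM, volumes in µL, input amount in mol
    (1 µM·µL = 1e-12 mol).  Recovery within ±10% of 1.0 passes; larger
    losses indicate adhesion, precipitation or aggregation.
    """
    if min(conc_red, conc_white, red_volume, white_volume) < 0:
        raise ValidationError("concentrations and volumes must be non-negative")
    if input_amount_mol <= 0:
        raise ValidationError("input amount must be positive")
    recovered_mol = (conc_red * red_volume + conc_white * white_volume) * 1e-12
    recovery = recovered_mol / input_amount_mol
    recovery_class = "pass" if abs(1.0 - recovery) <= RECOVERY_TOLERANCE else "fail"
    return recovery, recovery_class


def lred_from_total(
    input_amount_mol: float,
    lwhite: float,
    red_volume: float,
    white_volume: float,
) -> float:
    """Red-chamber concentration by difference from the total compound amount.

    With protein present the red aliquot is awkward to chromatograph, so the
    red amount is taken as (input − white amount) and divided by the red
    volume.  Units as in :func:`mass_balance`.
    """
    if input_amount_mol <= 0:
        raise ValidationError("input amount must be positive")
    if lwhite < 0:
        raise ValidationError("lwhite must be non-negative")
    white_mol = lwhite * white_volume * 1e-12
    red_mol = input_amount_mol - white_mol
    if red_mol < 0:
        raise ValidationError(
            f"white-chamber amount {white_mol:g} mol exceeds the input amount "
            f"{input_amount_mol:g} mol"
        )
    return red_mol / (red_volume * 1e-12)


# ---------------------------------------------------------------------------
# CSV I/O and end-to-end QC
# ---------------------------------------------------------------------------


def read_calibration_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CALIBRATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"calibration CSV missing columns: {missing}")
    return df


def read_samples_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sample CSV missing columns: {missing}")
    return df


def curve_from_frame(cal_df: pd.DataFrame, *, mode: str = "HPLC") -> CalibrationCurve:
    points = [
        CalibrationPoint(row.concentration_uM, row.peak_area, int(row.replicate))
        for row in cal_df.itertuples()
    ]
    return fit_calibration(points, mode=mode)


def evaluate_qc(
    cal_df: pd.DataFrame,
    samples_df: pd.DataFrame,
    red_volume: float,
    white_volume: float,
    input_amount_mol: float,
    *,
    mode: str = "HPLC",
    pair_by_sample: bool = True,
) -> QcReport:
    """Run the compound-only QC: fit calibration, form p_c, check recovery.

    Control-condition rows are paired red/white by ``sample_id`` (or pooled
    when ``pair_by_sample`` is false); p_c values are averaged over devices.
    Exclusion follows when either the p_c band or the recovery band fails.
    """
    curve = curve_from_frame(cal_df, mode=mode)
    control = samples_df[samples_df["condition"] == "control"]
    if control.empty:
        raise ValidationError("sample table contains no control-condition rows")

    def corrected(rows: pd.DataFrame) -> float:
        return float((rows["peak_area"] * rows["dilution_factor"]).mean())

    pcs = []
    if pair_by_sample:
        for sid, grp in control.groupby("sample_id"):
            red = grp[grp["chamber"] == "red"]
            white = grp[grp["chamber"] == "white"]
            if red.empty or white.empty:
                raise ValidationError(f"control sample {sid!r} lacks a red/white pair")
            if corrected(white) == 0:
                raise ValidationError(f"control sample {sid!r} has zero white area")
            pcs.append(corrected(red) / corrected(white))
    else:
        red = control[control["chamber"] == "red"]
        white = control[control["chamber"] == "white"]
        pcs.append(corrected(red) / corrected(white))
    pc = float(np.mean(pcs))
    pc_class = "pass" if PC_RANGE[0] <= pc <= PC_RANGE[1] else "fail"

    # Recovery from mean back-calculated concentrations over control devices.
    # LC–MS curves are in nM; mass_balance works in µM.
    unit_scale = 1e-3 if mode == "LCMS" else 1.0

    def mean_conc(chamber: str) -> float:
        rows = control[control["chamber"] == chamber]
        concs = [
            area_to_concentration(curve, row.peak_area, row.dilution_factor)
            for row in rows.itertuples()
        ]
        return float(np.mean(concs)) * unit_scale

    recovery, recovery_class = mass_balance(
        mean_conc("red"), mean_conc("white"), red_volume, white_volume, input_amount_mol
    )

    reasons = []
    if pc_class == "fail":
        reasons.append(f"pc out of range: {pc:.3f} outside [{PC_RANGE[0]}, {PC_RANGE[1]}]")
    if recovery_class == "fail":
        reasons.append(
            f"compound loss: recovery {recovery:.3f} deviates from 1.00 by more "
            f"than {RECOVERY_TOLERANCE:.0%}"
        )
    return QcReport(
        pc=pc,
        pc_class=pc_class,
        recovery=recovery,
        recovery_class=recovery_class,
        excluded=bool(reasons),
        reasons=tuple(reasons),
    )
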