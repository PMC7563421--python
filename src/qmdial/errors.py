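"""Exception taxonomy.

Validation errors (bad inputs) are distinct from domain errors (inputs that
are well-formed but physically uninformative or infeasible) so that callers —
in particular the CLI — can map them to different exit codes.
"""


class QmdialError(Exception):
    """Base class for all package errors."""


class ValidationError(QmdialError, ValueError):
    """Malformed or out-of-range input (non-finite, negative volume, ...)."""


class NoDetectableBindingError(QmdialError):
    """The measurement shows no enrichment over the protein-free control.

    K_D is undefined (formally unbounded): the estimator denominator vanishes
    at the no-binding observable value.
    """


class InfeasibleMeasurementError(QmdialError):
    """The measurement implies more complex than protein, or negative ligand.

    Such values cannot arise from the 1:1 equilibrium at any K_D ≥ 0 and
    usually indicate a calibration or handling problem.
    """


class PartialIntervalError(QmdialError):
    """One endpoint of a requested confidence interval leaves the valid domain."""

    def __init__(self, message: str, side: str):
        super().__init__(message)
        self.side = side  # "lower" or "upper"


class CalibrationError(QmdialError):
    """Calibration-curve fitting or back-calculation failure."""


class BelowBlankError(CalibrationError):
    """Peak area below the fitted blank (intercept): negative concentration."""
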