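"""Exception hierarchy.

All validation failures name the offending field so batch drivers can log
per-subject reasons instead of dying on the first malformed record.
"""


class CoawaveError(Exception):
    """Base class for all package errors."""


class ValidationError(CoawaveError, ValueError):
    """A domain-type invariant is violated (bad column, BP ordering, ...)."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class CalibrationError(CoawaveError, RuntimeError):
    """Central-pressure calibration cannot reach the measured mean BP."""


class DegenerateWaveformError(CalibrationError):
    """Flat area waveform: no pulsation to calibrate against."""


class TuningError(CoawaveError, RuntimeError):
    """Windkessel compliance tuning cannot bracket the target pulse pressure."""


class SimulationError(CoawaveError, RuntimeError):
    """1-D solver failure (CFL violation, blow-up)."""
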