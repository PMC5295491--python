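"""Central systolic blood pressure from aortic area waveforms.

The ascending-aortic area waveform is turned into a central pressure curve
through an exponential pressure–area law,

    p(t) = p_d * exp(beta * (A(t)/A_d - 1)),

where p_d is the brachial diastolic pressure, A_d the diastolic (minimum)
area and beta a dimensionless wall-stiffness scaling factor. beta is first set
to its theoretical maximum — the value at which the synthesized peak equals
the *brachial* systolic pressure,

    beta0 = ln(sbp/dbp) * A_d / (A_s - A_d),

and is then reduced iteratively until the time-mean of the synthesized curve
matches the measured oscillometric mean pressure. This exploits the
observation that mean and diastolic pressure are nearly constant along the
large arteries while systolic pressure is amplified towards the periphery, so
central SBP (the peak of the calibrated curve) is bounded above by brachial
SBP. The mean map beta -> time-mean(p(beta)) is strictly increasing for any
pulsatile area waveform, so bisection is guaranteed to converge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, DegenerateWaveformError, ValidationError
from .waveforms import AorticCycle, BrachialBP

__all__ = [
    "CentralPressureResult",
    "synthesize_pressure",
    "initial_beta",
    "calibrate_beta",
    "time_mean",
]


@dataclass(frozen=True)
class CentralPressureResult:
    """Calibrated central pressure curve.

    Attributes
    ----------
    pressure : ndarray
        Synthesized central pressure, mmHg, aligned with the cycle's samples.
    beta : float
        Calibrated dimensionless scaling factor.
    csbp : float
        Central systolic pressure = max(pressure), mmHg.
    mean_abs_error : float
        |time-mean(pressure) - measured mean BP|, mmHg.
    iterations : int
        Bisection iterations used.
    """

    pressure: np.ndarray
    beta: float
    csbp: float
    mean_abs_error: float
    iterations: int


def time_mean(time: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal time average of a sampled signal over its acquired window.

    Used both for the calibration target (mean of the synthesized pressure
    curve) and by the synthetic generator when it defines the measured mean BP,
    so that closed-loop recovery is exact.
    """
    return float(np.trapezoid(values, time) / (time[-1] - time[0]))


def synthesize_pressure(cycle: AorticCycle, dbp: float, beta: float) -> np.ndarray:
    """Exponential pressure–area transform p = dbp * exp(beta*(A/A_d - 1)).

    A_d is the global minimum of the area samples (earliest index on ties), so
    p >= dbp everywhere with equality at the diastolic-area sample.
    """
    if not beta > 0:
        raise ValidationError("beta", "must be positive")
    if not dbp > 0:
        raise ValidationError("dbp", "must be positive")
    a_d = cycle.diastolic_area
    return dbp * np.exp(beta * (cycle.area / a_d - 1.0))


def initial_beta(cycle: AorticCycle, bp: BrachialBP) -> float:
    """Theoretical maximum beta: synthesized peak equals brachial SBP.

    Inverts the exponential law at A = A_s:
    beta0 = ln(sbp/dbp) * A_d / (A_s - A_d). Because central SBP is in general
    lower than brachial SBP, the calibrated beta lies in (0, beta0].
    """
    a_d, a_s = cycle.diastolic_area, cycle.systolic_area
    if a_s <= a_d:
        raise DegenerateWaveformError(
            "flat area waveform (A_s = A_d): non-pulsatile input"
        )
    return float(np.log(bp.sbp / bp.dbp) * a_d / (a_s - a_d))


def calibrate_beta(
    cycle: AorticCycle,
    bp: BrachialBP,
    tol: float = 0.01,
    max_iter: int = 200,
) -> CentralPressureResult:
    """Calibrate beta so the synthesized mean pressure matches the measured mean.

    Bisection on beta in [1e-6, beta0]; the mean map is strictly increasing,
    so the root is unique. ``tol`` is on pressure (mmHg), not on beta; the
    interval is additionally narrowed until it no longer changes beta at
    double precision, so small ``tol`` values give correspondingly tight beta.

    Raises
    ------
    CalibrationError
        "calibration-infeasible": the mean at beta0 is below the measured
        mean BP (inconsistent BP/area inputs — the target cannot be reached by
        reducing beta).
    DegenerateWaveformError
        Flat area waveform.
    """
    if not bp.mbp > bp.dbp:
        raise CalibrationError("measured mean BP must exceed diastolic BP")
    beta0 = initial_beta(cycle, bp)

    def mean_at(beta: float) -> float:
        return time_mean(cycle.time, synthesize_pressure(cycle, bp.dbp, beta))

    if mean_at(beta0) < bp.mbp - tol:
        raise CalibrationError(
            "calibration-infeasible: synthesized mean at the maximal beta "
            f"({mean_at(beta0):.2f} mmHg) is below the measured mean BP "
            f"({bp.mbp:.2f} mmHg)"
        )

    lo, hi = 1e-6, beta0
    beta = beta0
    iterations = 0
    for iterations in range(1, max_iter + 1):
        beta = 0.5 * (lo + hi)
        m = mean_at(beta)
        if abs(m - bp.mbp) <= tol and (hi - lo) <= 1e-12 * max(1.0, beta):
            break
        if m < bp.mbp:
            lo = beta
        else:
            hi = beta
        if hi - lo <= np.finfo(float).eps * beta0:
            beta = 0.5 * (lo + hi)
            break

    pressure = synthesize_pressure(cycle, bp.dbp, beta)
    err = abs(time_mean(cycle.time, pressure) - bp.mbp)
    return CentralPressureResult(
        pressure=pressure,
        beta=float(beta),
        csbp=float(pressure.max()),
        mean_abs_error=float(err),
        iterations=iterations,
    )


def fallback_mean_bp(sbp: float, dbp: float) -> float:
    """Form-factor estimate dbp + (sbp-dbp)/3 for datasets lacking a measured
    mean. Never applied implicitly — callers must opt in."""
    return dbp + (sbp - dbp) / 3.0
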