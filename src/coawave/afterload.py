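"""Conventional vascular afterload measures.

Local wave speed from the Bramwell–Hill relation, aortic-root characteristic
impedance, cardiac output, Woods-unit arterial resistance, and total arterial
compliance (TAC) obtained by tuning a 2-element windkessel so its pulse
pressure matches the measured one. Blood density is fixed at 1060 kg/m^3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import TuningError, ValidationError
from .waveforms import AorticCycle

__all__ = [
    "RHO_BLOOD",
    "MMHG_PA",
    "StiffnessResult",
    "LoadResult",
    "bramwell_hill_pwv",
    "characteristic_impedance",
    "cardiac_output",
    "arterial_resistance",
    "windkessel_pressure",
    "tac_windkessel",
    "morphology_indices",
]

#: blood density, kg/m^3
RHO_BLOOD = 1060.0
#: 1 mmHg in Pa
MMHG_PA = 133.322
#: 1 Woods unit (mmHg·min/L) in mmHg·s/mL
WOODS_TO_MMHG_S_PER_ML = 0.06


@dataclass(frozen=True)
class StiffnessResult:
    pwv: float  # m/s
    zc: float  # mmHg·s/mL
    rho: float = RHO_BLOOD


@dataclass(frozen=True)
class LoadResult:
    cardiac_output: float  # L/min
    stroke_volume: float  # mL
    resistance: float  # Woods units (mmHg·min/L)
    resistance_indexed: float  # Woods·m^2
    tac_central: float  # mL/mmHg
    tac_brachial: float
    tac_central_indexed: float  # mL/mmHg/m^2
    tac_brachial_indexed: float
    pp_central: float  # mmHg
    pp_brachial: float


def bramwell_hill_pwv(a_d: float, delta_a: float, delta_p: float) -> float:
    """Local pulse wave velocity c = sqrt(A_d * dP / (rho * dA)), m/s.

    ``a_d`` is the diastolic area and ``delta_a`` the systolic–diastolic area
    excursion (same units — only their ratio enters); ``delta_p`` is the
    *central* pulse pressure (c-SBP − DBP) in mmHg. Single-site estimate,
    robust to early reflections unlike transit-time or flow-area methods.
    """
    if a_d <= 0 or delta_a <= 0 or delta_p <= 0:
        raise ValidationError("delta_a", "a_d, delta_a, delta_p must all be positive")
    return float(np.sqrt(a_d * delta_p * MMHG_PA / (RHO_BLOOD * delta_a)))


def characteristic_impedance(pwv: float, a_d: float) -> float:
    """Aortic-root characteristic impedance Zc = rho*c/A_d in mmHg·s/mL.

    ``pwv`` in m/s, ``a_d`` in cm^2. Computed in SI (Pa·s/m^3) and converted:
    /133.322 to mmHg·s/m^3, then /1e6 to per-mL.
    """
    if pwv <= 0 or a_d <= 0:
        raise ValidationError("pwv", "pwv and a_d must be positive")
    zc_si = RHO_BLOOD * pwv / (a_d * 1e-4)  # Pa·s/m^3
    return zc_si / MMHG_PA / 1e6


def cardiac_output(cycle: AorticCycle) -> tuple[float, float]:
    """(stroke volume mL, cardiac output L/min) from the aortic flow curve.

    SV is the trapezoidal integral of Q over the cycle (cyclic extension: the
    sample at t=period wraps to Q[0]); CO = SV * 60/period / 1000.
    """
    t = np.append(cycle.time, cycle.period)
    q = np.append(cycle.flow, cycle.flow[0])
    sv = float(np.trapezoid(q, t))
    if sv < 0:
        raise ValidationError("flow", "negative stroke volume: flow sign convention violated")
    co = sv * (60.0 / cycle.period) / 1000.0
    return sv, co


def arterial_resistance(mbp: float, co: float, bsa: Optional[float] = None):
    """Woods-unit resistance R = mean BP / CO, and R*BSA when BSA is given."""
    if not co > 0:
        raise ValidationError("co", "cardiac output must be positive")
    r = mbp / co
    return (r, r * bsa) if bsa is not None else (r, None)


# ---------------------------------------------------------------------------
# 2-element windkessel
# ---------------------------------------------------------------------------

def windkessel_pressure(cycle: AorticCycle, resistance: float, compliance: float) -> np.ndarray:
    """Periodic steady-state pressure of a 2-element windkessel, mmHg.

    Solves C dP/dt = Q(t) - P/R over one period with P(0) = P(T) in closed
    form via the integrating factor exp(t/RC):

        P(t) = e^{-t/tau} [ P(0) + (1/C) ∫_0^t e^{s/tau} Q ds ],  tau = R C,
        P(0) = e^{-T/tau}/(1 - e^{-T/tau}) * (1/C) ∫_0^T e^{s/tau} Q ds.

    ``resistance`` in Woods units (converted internally to mmHg·s/mL),
    ``compliance`` in mL/mmHg, flow in mL/s. The cycle is cyclically extended
    to t = T (flow wraps to its first sample). Returned samples align with
    ``cycle.time`` (the wrap sample is dropped).
    """
    if resistance <= 0 or compliance <= 0:
        raise ValidationError("compliance", "R and C must be positive")
    r = resistance * WOODS_TO_MMHG_S_PER_ML  # mmHg·s/mL
    tau = r * compliance
    t = np.append(cycle.time, cycle.period)
    q = np.append(cycle.flow, cycle.flow[0])
    dt = np.diff(t)
    # Exact exponential integrator for piecewise-linear Q on each interval:
    #   P_{k+1} = E_k P_k + b_k,  E_k = exp(-dt_k/tau),
    #   b_k = r [ (Q_{k+1} - Q_k E_k) - (tau/dt_k)(Q_{k+1} - Q_k)(1 - E_k) ].
    # Overflow-safe for arbitrarily small tau (E -> 0, b -> r Q_{k+1}).
    E = np.exp(-dt / tau)
    dq = np.diff(q)
    b = r * ((q[1:] - q[:-1] * E) - (tau / dt) * dq * (1.0 - E))
    n = b.size
    # periodicity: P_0 = sum_k E^{(suffix products after k)} b_k / (1 - prod E)
    suffix = np.concatenate((np.cumprod(E[::-1])[::-1][1:], [1.0]))
    prodE = float(np.prod(E))
    p0 = float(np.sum(suffix * b) / (1.0 - prodE))
    p = np.empty(n + 1)
    p[0] = p0
    for k in range(n):
        p[k + 1] = E[k] * p[k] + b[k]
    return p[:-1]


def _wk_pulse_pressure(cycle: AorticCycle, r_woods: float, c: float) -> float:
    p = windkessel_pressure(cycle, r_woods, c)
    return float(p.max() - p.min())


def tac_windkessel(
    cycle: AorticCycle,
    resistance: float,
    pulse_pressure: float,
    tol: float = 0.01,
) -> float:
    """Total arterial compliance, mL/mmHg, by 2-element windkessel tuning.

    The measured aortic flow curve and Woods-unit resistance drive the model;
    C is adjusted until the model's pulse pressure equals the measured one
    (central PP for TAC_central, brachial PP for TAC_brachial). PP_model(C) is
    strictly decreasing in C, so bisection on an expanding bracket
    [1e-3, 1e2] mL/mmHg (geometric x10 expansion, at most 4 times each way)
    converges; ``tol`` is on pulse pressure, mmHg.
    """
    if pulse_pressure <= 0:
        raise ValidationError("pulse_pressure", "must be positive")
    if resistance <= 0:
        raise ValidationError("resistance", "must be positive")
    if cycle.flow.max() == cycle.flow.min():
        raise TuningError("target-PP-unreachable: constant flow gives zero model pulse pressure")

    c_lo, c_hi = 1e-3, 1e2  # PP(c_lo) large, PP(c_hi) small
    for _ in range(4):
        if _wk_pulse_pressure(cycle, resistance, c_lo) >= pulse_pressure:
            break
        c_lo /= 10.0
    else:
        raise TuningError(
            "target-PP-unreachable: measured pulse pressure exceeds the model's "
            "pulse pressure at the minimal bracketed compliance"
        )
    for _ in range(4):
        if _wk_pulse_pressure(cycle, resistance, c_hi) <= pulse_pressure:
            break
        c_hi *= 10.0
    else:
        raise TuningError("target-PP-unreachable: bracket expansion failed on the high side")

    c = c_hi
    for _ in range(200):
        c = float(np.sqrt(c_lo * c_hi))  # geometric bisection over decades
        pp = _wk_pulse_pressure(cycle, resistance, c)
        if abs(pp - pulse_pressure) <= tol or c_hi / c_lo < 1 + 1e-13:
            break
        if pp > pulse_pressure:
            c_lo = c
        else:
            c_hi = c
    return c


def morphology_indices(
    diam_transverse: Optional[float],
    diam_isthmus: Optional[float],
    diam_descending: Optional[float],
) -> tuple[Optional[float], Optional[float], bool]:
    """Arch morphology ratios (ti, ci, recoarctation_suspected).

    ti = transverse arch / descending aorta diameter (arch hypoplasia index);
    ci = isthmus (repair site) / descending aorta diameter (coarctation
    index). ci < 0.7 flags suspected recoarctation. Missing diameters yield
    None indices without error.
    """
    for name, v in (
        ("diam_transverse", diam_transverse),
        ("diam_isthmus", diam_isthmus),
        ("diam_descending", diam_descending),
    ):
        if v is not None and not v > 0:
            raise ValidationError(name, "diameters must be positive")
    ti = ci = None
    if diam_descending is not None:
        if diam_transverse is not None:
            ti = diam_transverse / diam_descending
        if diam_isthmus is not None:
            ci = diam_isthmus / diam_descending
    return ti, ci, (ci is not None and ci < 0.7)
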