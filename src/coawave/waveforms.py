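"""Domain types for single-cycle aortic waveforms and their preprocessing.

The raw input to every analysis stage is one cardiac cycle of ascending-aortic
cross-sectional area A(t) (cm^2) and volumetric flow Q(t) (mL/s), uniformly
sampled from the R-wave trigger (t = 0), together with oscillometric brachial
pressures. Typical MRI-derived data are sampled at ~9.6 ms, but any uniform
grid is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

from .errors import ValidationError

#: minimum number of samples in a cycle
MIN_SAMPLES = 16

#: tolerance on grid uniformity, seconds
DT_ATOL = 1e-9


@dataclass(frozen=True)
class AorticCycle:
    """One cardiac cycle of uniformly sampled aortic area and flow.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds, starting at 0 (the R-wave trigger), strictly
        increasing with uniform spacing ``dt``.
    area : ndarray
        Cross-sectional area in cm^2, strictly positive.
    flow : ndarray
        Volumetric flow in mL/s (= cm^3/s).
    period : float
        Cardiac cycle length in seconds; defaults to ``time[-1] + dt``.
    """

    time: np.ndarray
    area: np.ndarray
    flow: np.ndarray
    period: float = field(default=0.0)

    def __post_init__(self):
        time = np.ascontiguousarray(self.time, dtype=float)
        area = np.ascontiguousarray(self.area, dtype=float)
        flow = np.ascontiguousarray(self.flow, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "area", area)
        object.__setattr__(self, "flow", flow)
        n = time.size
        if area.size != n or flow.size != n:
            raise ValidationError("time", "time, area, flow must have identical length")
        if n < MIN_SAMPLES:
            raise ValidationError("time", f"need at least {MIN_SAMPLES} samples, got {n}")
        for name, arr in (("time", time), ("area", area), ("flow", flow)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(name, "non-finite values")
        if abs(time[0]) > DT_ATOL:
            raise ValidationError("time", "time[0] must be 0 (R-wave trigger origin)")
        steps = np.diff(time)
        if np.any(steps <= 0):
            raise ValidationError("time", "time must be strictly increasing")
        if np.ptp(steps) > DT_ATOL:
            raise ValidationError("time", "non-uniform time grid")
        if np.any(area <= 0):
            raise ValidationError("area", "non-positive area")
        if self.period == 0.0:
            object.__setattr__(self, "period", float(time[-1] + steps[0]))
        if self.period <= time[-1]:
            raise ValidationError("period", "period must exceed the last sample time")

    @property
    def dt(self) -> float:
        """Uniform sampling interval, seconds."""
        return float(self.time[1] - self.time[0])

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def diastolic_area(self) -> float:
        """A_d: global minimum of the area samples, cm^2."""
        return float(self.area.min())

    @property
    def systolic_area(self) -> float:
        """A_s: global maximum of the area samples, cm^2."""
        return float(self.area.max())

    @property
    def heart_rate(self) -> float:
        """beats/min, derived as 60/period."""
        return 60.0 / self.period


@dataclass(frozen=True)
class BrachialBP:
    """Oscillometric brachial pressures in mmHg: systolic (p-SBP), diastolic
    and measured mean. Must satisfy dbp < mbp < sbp."""

    sbp: float
    dbp: float
    mbp: float

    def __post_init__(self):
        for name in ("sbp", "dbp", "mbp"):
            if not getattr(self, name) > 0:
                raise ValidationError(name, "pressures must be positive")
        if not (self.dbp < self.mbp < self.sbp):
            raise ValidationError(
                "mbp", f"BP ordering violated: need dbp < mbp < sbp, "
                f"got dbp={self.dbp}, mbp={self.mbp}, sbp={self.sbp}"
            )

    @property
    def pulse_pressure(self) -> float:
        """Brachial pulse pressure sbp - dbp, mmHg."""
        return self.sbp - self.dbp


@dataclass(frozen=True)
class SubjectRecord:
    """One study subject: identity, group, body size, brachial pressures, one
    aortic cycle, and optional LV mass / arch diameters."""

    id: str
    group: str  # "patient" | "control"
    bsa: float  # m^2
    bp: BrachialBP
    cycle: AorticCycle
    sex: str = "M"  # "M" | "F"
    age: float = 0.0  # years
    lvm: Optional[float] = None  # grams
    diam_transverse: Optional[float] = None  # mm
    diam_isthmus: Optional[float] = None
    diam_descending: Optional[float] = None

    def __post_init__(self):
        if self.group not in ("patient", "control"):
            raise ValidationError("group", f"unknown group {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValidationError("sex", f"unknown sex {self.sex!r}")
        if not self.bsa > 0:
            raise ValidationError("bsa", "BSA must be positive")
        for name in ("lvm", "diam_transverse", "diam_isthmus", "diam_descending"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(name, "must be positive when present")

    @property
    def heart_rate(self) -> float:
        return self.cycle.heart_rate


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def resample_uniform(cycle: AorticCycle, dt_new: float) -> AorticCycle:
    """Linearly interpolate area and flow onto a new uniform grid.

    ``dt_new`` must be positive and no coarser than period/16 so the resampled
    cycle still satisfies the minimum-length invariant. The endpoints of the
    acquired window are preserved; the grid spans [0, time[-1]].
    """
    if not dt_new > 0:
        raise ValidationError("dt_new", "must be positive")
    if dt_new > cycle.period / MIN_SAMPLES:
        raise ValidationError("dt_new", f"too coarse: must be <= period/{MIN_SAMPLES}")
    if abs(dt_new - cycle.dt) < DT_ATOL:
        return cycle
    n_new = int(np.floor(cycle.time[-1] / dt_new + 1e-12)) + 1
    t_new = np.arange(n_new) * dt_new
    area = np.interp(t_new, cycle.time, cycle.area)
    flow = np.interp(t_new, cycle.time, cycle.flow)
    return AorticCycle(time=t_new, area=area, flow=flow, period=cycle.period)


def smooth(cycle: AorticCycle, window: int, polyorder: int = 3) -> AorticCycle:
    """Savitzky–Golay smoothing of area and flow (time grid unchanged).

    ``window`` must be odd and at least ``polyorder + 2``; polynomials up to
    ``polyorder`` are reproduced exactly. Area positivity is re-checked after
    filtering.
    """
    if window % 2 == 0 or window < polyorder + 2:
        raise ValidationError(
            "window", f"window must be odd and >= polyorder+2, got {window}"
        )
    area = savgol_filter(cycle.area, window, polyorder)
    flow = savgol_filter(cycle.flow, window, polyorder)
    return AorticCycle(time=cycle.time, area=area, flow=flow, period=cycle.period)


def increments(cycle: AorticCycle) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample first differences (dA, dQ) of area and flow.

    Waves are treated as summations of incremental wavefronts, so the analysis
    operates on successive differences rather than derivatives. The n-1
    increments are attributed to interval midpoints (see
    :func:`increment_midtimes`); ``sum(dA)`` telescopes exactly to
    ``area[-1] - area[0]``.
    """
    return np.diff(cycle.area), np.diff(cycle.flow)


def increment_midtimes(cycle: AorticCycle) -> np.ndarray:
    """Midpoint times (s) of the n-1 sampling intervals."""
    return 0.5 * (cycle.time[1:] + cycle.time[:-1])


def with_waveforms(cycle: AorticCycle, area=None, flow=None) -> AorticCycle:
    """Copy of ``cycle`` with area and/or flow replaced (revalidated)."""
    return replace(
        cycle,
        area=cycle.area if area is None else area,
        flow=cycle.flow if flow is None else flow,
    )
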