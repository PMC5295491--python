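"""Noninvasive wave intensity analysis in the area–flow domain.

Arterial waves are treated as summations of incremental wavefronts. Using the
local wave speed c, per-sample increments of area and flow split exactly into
forward- and backward-travelling components:

    dA± = (dA ± dQ/c) / 2,      dQ± = (dQ ± c·dA) / 2,

with c in cm/s so that dQ± = ±c·dA±. Wave intensity is defined per increment
as dI = dA·dQ and dI± = dA±·dQ±, giving cm^5 on summation over a wave; the
cross terms cancel, so dI = dI+ + dI- holds identically with dI+ >= 0 and
dI- <= 0. Four wave types are classified from the sign of the separated area
increments over each detected run: forward/backward compression waves push
area (pressure) up, expansion waves pull it down. The backward compression
wave (BCW) — rising area with decelerating flow — is the signature of a
reflected wave returning to the aortic root. The reflection magnitude is the
amplitude ratio of the backward to the forward separated area waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError
from .waveforms import AorticCycle, increment_midtimes, increments

__all__ = [
    "SeparatedIncrements",
    "DetectedWave",
    "WaveAnalysis",
    "separate",
    "cumulate_area",
    "detect_waves",
    "bcw_summary",
    "reflection_magnitude",
    "analyze_cycle",
]

#: default wave-support threshold: fraction of each channel's peak |dI±|
MIN_PEAK_FRACTION = 0.05
#: systole gate: flow above this fraction of peak flow
SYSTOLE_FLOW_FRACTION = 0.05


@dataclass(frozen=True)
class SeparatedIncrements:
    """Forward/backward split of the per-sample area and flow increments."""

    dA_plus: np.ndarray  # cm^2
    dA_minus: np.ndarray
    dQ_plus: np.ndarray  # cm^3/s
    dQ_minus: np.ndarray
    dI: np.ndarray  # cm^5 per increment (dA*dQ)
    dI_plus: np.ndarray
    dI_minus: np.ndarray
    c_cm_s: float  # wave speed used for the split
    t_mid: np.ndarray  # s, increment midpoints


@dataclass(frozen=True)
class DetectedWave:
    """One contiguous wave: kind in {FCW, FEW, BCW, BEW}, support [t_onset,
    t_end], peak time, magnitude = |sum dI±| over the support (cm^5)."""

    kind: str
    t_onset: float
    t_peak: float
    t_end: float
    magnitude: float
    peak_intensity: float


@dataclass(frozen=True)
class WaveAnalysis:
    separated: SeparatedIncrements
    waves: list[DetectedWave]
    reflection_magnitude: float
    bcw_magnitude: float  # cm^5, 0 when absent
    bcw_time: Optional[float]  # s, None when absent
    area_forward_amplitude: float  # cm^2
    area_backward_amplitude: float


def separate(dA: np.ndarray, dQ: np.ndarray, pwv: float, t_mid=None) -> SeparatedIncrements:
    """Split increments into forward (+) and backward (−) components.

    ``pwv`` is the local wave speed in m/s (converted to cm/s internally so
    units match the cm^2 / cm^3/s increments). The split is exact:
    dA+ + dA- = dA, dQ+ + dQ- = dQ and dI+ + dI- = dI by construction.
    """
    if not pwv > 0:
        raise ValidationError("pwv", "wave speed must be positive")
    dA = np.asarray(dA, float)
    dQ = np.asarray(dQ, float)
    if dA.shape != dQ.shape:
        raise ValidationError("dQ", "increment sequences must have equal length")
    c = pwv * 100.0  # cm/s
    dA_plus = 0.5 * (dA + dQ / c)
    dA_minus = 0.5 * (dA - dQ / c)
    dQ_plus = 0.5 * (dQ + c * dA)
    dQ_minus = 0.5 * (dQ - c * dA)
    if t_mid is None:
        t_mid = np.arange(dA.size, dtype=float)
    return SeparatedIncrements(
        dA_plus=dA_plus,
        dA_minus=dA_minus,
        dQ_plus=dQ_plus,
        dQ_minus=dQ_minus,
        dI=dA * dQ,
        dI_plus=dA_plus * dQ_plus,
        dI_minus=dA_minus * dQ_minus,
        c_cm_s=c,
        t_mid=np.asarray(t_mid, float),
    )


def cumulate_area(separated: SeparatedIncrements) -> tuple[np.ndarray, np.ndarray]:
    """Forward and backward area waveforms by cumulative summation of dA±.

    Both start at 0; their sum reproduces area - area[0] exactly (telescoping).
    Arrays have length n (a leading zero is prepended) so they align with the
    original samples.
    """
    a_plus = np.concatenate(([0.0], np.cumsum(separated.dA_plus)))
    a_minus = np.concatenate(([0.0], np.cumsum(separated.dA_minus)))
    return a_plus, a_minus


def _runs(mask: np.ndarray):
    """Contiguous True runs of a boolean mask as (start, stop) index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_waves(
    separated: SeparatedIncrements, min_peak_fraction: float = MIN_PEAK_FRACTION
) -> list[DetectedWave]:
    """Detect and classify waves in the separated intensity channels.

    Waves are maximal contiguous runs where |dI±| exceeds ``min_peak_fraction``
    times that channel's own peak. Forward waves come from dI+ and are
    compression (FCW) when the run-integral of dA+ is positive, expansion
    (FEW) otherwise; backward waves from dI- are classified by the sign of the
    dA- run-integral (BCW when positive). Magnitude is the area under the
    separated intensity over the run, |sum dI±|, in cm^5. An empty list is
    returned for all-zero input.
    """
    waves: list[DetectedWave] = []
    t = separated.t_mid
    # a channel whose peak is at rounding level relative to the other carries
    # no physical wave (e.g. the backward channel of a pure forward run)
    floor = 1e-12 * max(
        np.abs(separated.dI_plus).max(initial=0.0),
        np.abs(separated.dI_minus).max(initial=0.0),
    )
    for channel, comp_kind, exp_kind, da in (
        (separated.dI_plus, "FCW", "FEW", separated.dA_plus),
        (separated.dI_minus, "BCW", "BEW", separated.dA_minus),
    ):
        peak = np.abs(channel).max()
        if peak <= floor:
            continue
        for start, stop in _runs(np.abs(channel) > min_peak_fraction * peak):
            seg = channel[start:stop]
            ipk = start + int(np.abs(seg).argmax())
            kind = comp_kind if float(da[start:stop].sum()) > 0 else exp_kind
            waves.append(
                DetectedWave(
                    kind=kind,
                    t_onset=float(t[start]),
                    t_peak=float(t[ipk]),
                    t_end=float(t[stop - 1]),
                    magnitude=float(abs(seg.sum())),
                    peak_intensity=float(np.abs(seg).max()),
                )
            )
    waves.sort(key=lambda w: w.t_onset)
    return waves


def bcw_summary(
    waves: list[DetectedWave], systole_end: Optional[float] = None
) -> tuple[float, Optional[float]]:
    """(magnitude, peak time) of the dominant backward compression wave.

    Among BCWs peaking within systole (``t_peak <= systole_end`` when a gate
    is given), the largest-magnitude one is selected; its arrival time is the
    time of peak |dI-|. Returns (0.0, None) when no BCW qualifies.
    """
    bcws = [w for w in waves if w.kind == "BCW"]
    if systole_end is not None:
        bcws = [w for w in bcws if w.t_peak <= systole_end]
    if not bcws:
        return 0.0, None
    best = max(bcws, key=lambda w: w.magnitude)
    return best.magnitude, best.t_peak


def reflection_magnitude(a_plus: np.ndarray, a_minus: np.ndarray) -> float:
    """Amplitude ratio (max-min) of backward to forward area waveforms."""
    amp_f = float(np.ptp(a_plus))
    if amp_f == 0.0:
        raise ValidationError("a_plus", "flat forward area waveform: separation failed")
    return float(np.ptp(a_minus)) / amp_f


def systole_end_time(cycle: AorticCycle, flow_fraction: float = SYSTOLE_FLOW_FRACTION) -> float:
    """End of systolic ejection: last time of the contiguous run, containing
    the flow peak, where flow exceeds ``flow_fraction`` * peak flow."""
    q = cycle.flow
    thresh = flow_fraction * q.max()
    ipk = int(q.argmax())
    j = ipk
    while j + 1 < q.size and q[j + 1] > thresh:
        j += 1
    return float(cycle.time[j])


def analyze_cycle(
    cycle: AorticCycle,
    pwv: float,
    min_peak_fraction: float = MIN_PEAK_FRACTION,
    systole_flow_fraction: float = SYSTOLE_FLOW_FRACTION,
) -> WaveAnalysis:
    """Full wave-intensity analysis of one cycle at a given wave speed.

    Convenience driver: increments -> separation -> wave detection -> BCW
    summary (systole-gated) -> reflection magnitude.
    """
    dA, dQ = increments(cycle)
    sep = separate(dA, dQ, pwv, t_mid=increment_midtimes(cycle))
    waves = detect_waves(sep, min_peak_fraction)
    bcw_mag, bcw_time = bcw_summary(waves, systole_end_time(cycle, systole_flow_fraction))
    a_plus, a_minus = cumulate_area(sep)
    rm = reflection_magnitude(a_plus, a_minus)
    return WaveAnalysis(
        separated=sep,
        waves=waves,
        reflection_magnitude=rm,
        bcw_magnitude=bcw_mag,
        bcw_time=bcw_time,
        area_forward_amplitude=float(np.ptp(a_plus)),
        area_backward_amplitude=float(np.ptp(a_minus)),
    )
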