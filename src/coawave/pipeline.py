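"""Batch driver and study-level statistics.

Runs the full per-subject chain (central-pressure calibration -> stiffness and
load measures -> wave intensity), classifies central/brachial systolic
hypertension, summarises groups (Welch t-tests; geometric means for
log-transformed metrics) and fits the adjusted LV-mass regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import afterload as af
from . import central_pressure as cp
from . import wave_intensity as wia
from .errors import CoawaveError, ValidationError
from .waveforms import SubjectRecord, smooth

log = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "SubjectMetrics",
    "analyze_subject",
    "analyze_cohort",
    "metrics_table",
    "summarize_groups",
    "lvm_regression",
    "CENTRAL_HTN_MMHG",
    "BRACHIAL_HTN_MMHG",
]

#: central systolic hypertension threshold, mmHg (c-SBP strictly above)
CENTRAL_HTN_MMHG = 125.0
#: brachial systolic hypertension threshold, mmHg (p-SBP strictly above)
BRACHIAL_HTN_MMHG = 140.0


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the per-subject chain. Smoothing is off by default."""

    calibration_tol: float = 0.01  # mmHg on mean pressure
    tac_tol: float = 0.01  # mmHg on windkessel pulse pressure
    min_peak_fraction: float = wia.MIN_PEAK_FRACTION
    systole_flow_fraction: float = wia.SYSTOLE_FLOW_FRACTION
    smooth_window: int = 0  # 0 disables smoothing
    smooth_polyorder: int = 3


@dataclass
class SubjectMetrics:
    """Per-subject derived metrics (one row of the study table)."""

    id: str
    group: str
    bsa: float
    sex: str
    age: float
    csbp: float
    psbp: float
    dbp: float
    mbp: float
    beta: float
    pwv: float  # m/s
    zc: float  # mmHg*s/mL
    stroke_volume: float  # mL
    cardiac_output: float  # L/min
    cardiac_index: float  # L/min/m^2
    resistance: float  # Woods units
    resistance_indexed: float
    tac_central: float  # mL/mmHg
    tac_brachial: float
    tac_central_indexed: float
    tac_brachial_indexed: float
    pp_central: float
    pp_brachial: float
    bcw_magnitude: float  # cm^5
    bcw_magnitude_log: Optional[float]
    bcw_time: Optional[float]
    fcw_magnitude: float
    few_magnitude: float
    reflection_magnitude: float
    lvm: Optional[float]
    ti: Optional[float]
    ci: Optional[float]
    recoarctation_suspected: bool
    central_htn: bool
    brachial_htn: bool


def analyze_subject(record: SubjectRecord, config: AnalysisConfig = AnalysisConfig()) -> SubjectMetrics:
    """Run the full hemodynamic chain on one subject.

    Order matters: the calibrated central pressure feeds the Bramwell–Hill
    wave speed (central pulse pressure, never brachial), which feeds both the
    characteristic impedance and the wave separation; resistance feeds the
    windkessel compliance tuning with central and brachial pulse pressures in
    turn. Stage errors propagate annotated with the subject id.
    """
    try:
        cycle = record.cycle
        if config.smooth_window:
            cycle = smooth(cycle, config.smooth_window, config.smooth_polyorder)

        central = cp.calibrate_beta(cycle, record.bp, tol=config.calibration_tol)
        pp_central = central.csbp - record.bp.dbp
        pp_brachial = record.bp.pulse_pressure

        a_d = cycle.diastolic_area
        pwv = af.bramwell_hill_pwv(a_d, cycle.systolic_area - a_d, pp_central)
        zc = af.characteristic_impedance(pwv, a_d)

        sv, co = af.cardiac_output(cycle)
        resistance, resistance_idx = af.arterial_resistance(record.bp.mbp, co, record.bsa)
        tac_c = af.tac_windkessel(cycle, resistance, pp_central, tol=config.tac_tol)
        tac_b = af.tac_windkessel(cycle, resistance, pp_brachial, tol=config.tac_tol)

        analysis = wia.analyze_cycle(
            cycle,
            pwv,
            min_peak_fraction=config.min_peak_fraction,
            systole_flow_fraction=config.systole_flow_fraction,
        )
        fcw = max((w.magnitude for w in analysis.waves if w.kind == "FCW"), default=0.0)
        few = max((w.magnitude for w in analysis.waves if w.kind == "FEW"), default=0.0)

        ti, ci, recoarc = af.morphology_indices(
            record.diam_transverse, record.diam_isthmus, record.diam_descending
        )
    except CoawaveError as err:
        raise type(err)(f"subject {record.id}: {err}") from err

    return SubjectMetrics(
        id=record.id,
        group=record.group,
        bsa=record.bsa,
        sex=record.sex,
        age=record.age,
        csbp=central.csbp,
        psbp=record.bp.sbp,
        dbp=record.bp.dbp,
        mbp=record.bp.mbp,
        beta=central.beta,
        pwv=pwv,
        zc=zc,
        stroke_volume=sv,
        cardiac_output=co,
        cardiac_index=co / record.bsa,
        resistance=resistance,
        resistance_indexed=resistance_idx,
        tac_central=tac_c,
        tac_brachial=tac_b,
        tac_central_indexed=tac_c / record.bsa,
        tac_brachial_indexed=tac_b / record.bsa,
        pp_central=pp_central,
        pp_brachial=pp_brachial,
        bcw_magnitude=analysis.bcw_magnitude,
        bcw_magnitude_log=(
            math.log(analysis.bcw_magnitude) if analysis.bcw_magnitude > 0 else None
        ),
        bcw_time=analysis.bcw_time,
        fcw_magnitude=fcw,
        few_magnitude=few,
        reflection_magnitude=analysis.reflection_magnitude,
        lvm=record.lvm,
        ti=ti,
        ci=ci,
        recoarctation_suspected=recoarc,
        central_htn=central.csbp > CENTRAL_HTN_MMHG,
        brachial_htn=record.bp.sbp > BRACHIAL_HTN_MMHG,
    )


def analyze_cohort(
    records: Iterable[SubjectRecord], config: AnalysisConfig = AnalysisConfig()
) -> tuple[list[SubjectMetrics], list[tuple[str, str]]]:
    """Analyze every subject; failures are collected (id, reason), never silent."""
    metrics: list[SubjectMetrics] = []
    failures: list[tuple[str, str]] = []
    for rec in records:
        try:
            metrics.append(analyze_subject(rec, config))
        except CoawaveError as err:
            log.warning("subject %s failed: %s", rec.id, err)
            failures.append((rec.id, str(err)))
    return metrics, failures


def metrics_table(metrics: Sequence[SubjectMetrics]) -> pd.DataFrame:
    """Tidy one-row-per-subject DataFrame."""
    return pd.DataFrame([asdict(m) for m in metrics])


#: metrics reported as geometric means after natural-log transform
DEFAULT_LOG_METRICS = frozenset({"bcw_magnitude"})


def _group_ci(values: np.ndarray) -> tuple[float, float, float]:
    """(mean, lo, hi): mean and 95% t-interval."""
    m = float(np.mean(values))
    if values.size < 2:
        return m, m, m
    half = float(stats.t.ppf(0.975, values.size - 1) * stats.sem(values))
    return m, m - half, m + half


def summarize_groups(
    metrics: Sequence[SubjectMetrics],
    log_metrics: frozenset = DEFAULT_LOG_METRICS,
    variance_ratio_welch: float = 2.0,
) -> pd.DataFrame:
    """Group summary table: means with 95% CIs and two-sample t-tests.

    Continuous metrics get patient/control means with 95% confidence
    intervals — geometric means (natural-log transform) for metrics in
    ``log_metrics`` — plus both the Welch and the pooled t-test p-value; the
    reported ``p_value`` column follows a variance-ratio pre-check (Welch when
    the larger group variance exceeds ``variance_ratio_welch`` times the
    smaller). Binary metrics get counts, proportions and a two-proportion
    z-test. Requires >= 2 subjects per group.
    """
    table = metrics_table(metrics)
    for grp in ("patient", "control"):
        if (table["group"] == grp).sum() < 2:
            raise ValidationError("group", f"need >= 2 subjects in group {grp!r}")
    pat = table[table["group"] == "patient"]
    ctl = table[table["group"] == "control"]

    skip = {"id", "group", "sex", "bcw_magnitude_log"}
    rows = []
    for col in table.columns:
        if col in skip:
            continue
        if table[col].dtype == bool:
            np_, nc_ = int(pat[col].sum()), int(ctl[col].sum())
            count = np.array([np_, nc_])
            nobs = np.array([len(pat), len(ctl)])
            if count.sum() in (0, nobs.sum()) or np_ / len(pat) == nc_ / len(ctl):
                p = 1.0  # no variance: identical proportions
            else:
                _, p = sm.stats.proportions_ztest(count, nobs)
            rows.append(
                dict(metric=col, kind="binary",
                     patient_mean=np_ / len(pat), control_mean=nc_ / len(ctl),
                     patient_lo=np.nan, patient_hi=np.nan,
                     control_lo=np.nan, control_hi=np.nan,
                     p_value=float(p), p_welch=np.nan, p_pooled=np.nan)
            )
            continue
        pv = pd.to_numeric(pat[col], errors="coerce").dropna().to_numpy(float)
        cv = pd.to_numeric(ctl[col], errors="coerce").dropna().to_numpy(float)
        if pv.size < 2 or cv.size < 2:
            continue
        logged = col in log_metrics
        if logged:
            if np.any(pv <= 0) or np.any(cv <= 0):
                raise ValidationError(col, "nonpositive value under log transform")
            pv, cv = np.log(pv), np.log(cv)
        p_welch = float(stats.ttest_ind(pv, cv, equal_var=False).pvalue)
        p_pooled = float(stats.ttest_ind(pv, cv, equal_var=True).pvalue)
        var_ratio = max(pv.var(ddof=1), cv.var(ddof=1)) / max(
            min(pv.var(ddof=1), cv.var(ddof=1)), 1e-300
        )
        p_used = p_welch if var_ratio > variance_ratio_welch else p_pooled
        pm, plo, phi = _group_ci(pv)
        cm, clo, chi = _group_ci(cv)
        if logged:
            pm, plo, phi, cm, clo, chi = (math.exp(v) for v in (pm, plo, phi, cm, clo, chi))
        rows.append(
            dict(metric=col, kind="geometric" if logged else "normal",
                 patient_mean=pm, control_mean=cm,
                 patient_lo=plo, patient_hi=phi, control_lo=clo, control_hi=chi,
                 p_value=p_used, p_welch=p_welch, p_pooled=p_pooled)
        )
    return pd.DataFrame(rows)


def lvm_regression(
    metrics: Sequence[SubjectMetrics],
    predictor: str = "bcw_magnitude_log",
    adjusters: Sequence[str] = ("bsa", "age", "sex", "group"),
) -> pd.DataFrame:
    """OLS of LV mass (g) on one hemodynamic predictor plus adjusters.

    Mirrors an adjusted univariable design: LVM ~ predictor + BSA + age + sex
    (+ case/control), returning coefficients, standard errors, t and p values.
    Categorical adjusters are coded 0/1 (sex: male=1; group: patient=1).
    Requires LVM on >= 10 subjects; rank deficiency is reported with the
    offending columns.
    """
    table = metrics_table(metrics)
    table = table[table["lvm"].notna()]
    if predictor not in table.columns:
        raise ValidationError(predictor, "unknown predictor column")
    table = table[pd.to_numeric(table[predictor], errors="coerce").notna()]
    if len(table) < 10:
        raise ValidationError("lvm", f"need LVM on >= 10 subjects, have {len(table)}")

    X = pd.DataFrame({predictor: pd.to_numeric(table[predictor])})
    for adj in adjusters:
        if adj == "sex":
            X["sex_male"] = (table["sex"] == "M").astype(float)
        elif adj == "group":
            X["group_patient"] = (table["group"] == "patient").astype(float)
        else:
            X[adj] = pd.to_numeric(table[adj])
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        constant_cols = [c for c in X.columns if c != "const" and X[c].nunique() == 1]
        raise ValidationError(
            "design", f"rank-deficient design matrix (rank {rank} < {X.shape[1]}); "
            f"constant columns: {constant_cols}"
        )
    fit = sm.OLS(table["lvm"].to_numpy(float), X).fit()
    return pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p_value": fit.pvalues,
        }
    )
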