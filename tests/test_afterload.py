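"""Stiffness, resistance and windkessel compliance."""

import numpy as np
import pytest

from coawave.afterload import (
    MMHG_PA,
    RHO_BLOOD,
    WOODS_TO_MMHG_S_PER_ML,
    arterial_resistance,
    bramwell_hill_pwv,
    cardiac_output,
    characteristic_impedance,
    morphology_indices,
    tac_windkessel,
    windkessel_pressure,
)
from coawave.errors import TuningError, ValidationError
from coawave.synthetic import make_forward_wave
from coawave.waveforms import AorticCycle


def wk2_oracle(cycle, r_woods, c, n_cycles=14, substeps=40):
    """Independent fine-grid RK4 time-stepper for the 2-element windkessel,
    run to periodic convergence from a crude initial pressure.

    Returns (t, p) for the last period on the fine grid."""
    r = r_woods * WOODS_TO_MMHG_S_PER_ML
    t = np.append(cycle.time, cycle.period)
    q = np.append(cycle.flow, cycle.flow[0])

    def qf(tt):
        return np.interp(tt % cycle.period, t, q)

    def rhs(tt, p):
        return (qf(tt) - p / r) / c

    dt = cycle.dt / substeps
    n_per = int(round(cycle.period / dt))
    p = float(np.mean(q)) * r
    # transient decays over the first n_cycles-1 periods; record the last one
    tt = 0.0
    total = n_cycles * n_per
    rec = np.empty(n_per + 1)
    for i in range(total):
        if i >= total - n_per - 1:
            rec[i - (total - n_per - 1)] = p
        k1 = rhs(tt, p)
        k2 = rhs(tt + dt / 2, p + dt / 2 * k1)
        k3 = rhs(tt + dt / 2, p + dt / 2 * k2)
        k4 = rhs(tt + dt, p + dt * k3)
        p += dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        tt += dt
    return np.arange(rec.size) * dt, rec


class TestUnitChecks:
    def test_bramwell_hill_hand_converted_value(self):
        # sqrt(5 cm^2 * 40 mmHg * 133.322 Pa/mmHg / (1060 kg/m^3 * 1 cm^2))
        c = bramwell_hill_pwv(a_d=5.0, delta_a=1.0, delta_p=40.0)
        assert c == pytest.approx(np.sqrt(5.0 * 40.0 * 133.322 / 1060.0), rel=1e-12)
        assert c == pytest.approx(5.02, abs=0.01)

    def test_pwv_square_root_scaling_and_limits(self):
        base = bramwell_hill_pwv(5.0, 1.0, 40.0)
        assert bramwell_hill_pwv(5.0, 1.0, 160.0) == pytest.approx(2 * base, rel=1e-12)
        assert bramwell_hill_pwv(5.0, 1e9, 40.0) < 1e-3

    def test_characteristic_impedance_hand_converted_value(self):
        zc = characteristic_impedance(pwv=5.0, a_d=5.0)
        assert zc == pytest.approx(1060.0 * 5.0 / 5e-4 / 133.322 / 1e6, rel=1e-12)
        assert zc == pytest.approx(0.0795, abs=0.0005)

    def test_zc_identity_recovers_blood_density_in_si(self):
        for pwv, a_d in [(4.0, 3.5), (6.5, 7.2)]:
            zc = characteristic_impedance(pwv, a_d)
            zc_si = zc * MMHG_PA * 1e6
            assert zc_si * (a_d * 1e-4) / pwv == pytest.approx(RHO_BLOOD, rel=1e-12)
        assert characteristic_impedance(5.0, 10.0) == pytest.approx(
            characteristic_impedance(5.0, 5.0) / 2, rel=1e-12
        )


class TestCardiacOutputAndResistance:
    def test_rectangular_flow_arithmetic(self):
        n, dt = 100, 0.01
        t = np.arange(n) * dt
        flow = np.where(t < 0.3, 300.0, 0.0)
        flow[30] = 0.0
        cyc = AorticCycle(time=t, area=np.full(n, 5.0), flow=flow, period=1.0)
        sv, co = cardiac_output(cyc)
        assert sv == pytest.approx(90.0, rel=0.02)
        assert co == pytest.approx(sv * 60 / 1000, rel=1e-12)

    def test_resistance_arithmetic_and_indexing(self):
        r, r_idx = arterial_resistance(90.0, 5.0, bsa=2.0)
        assert r == pytest.approx(18.0)
        assert r_idx == pytest.approx(36.0)
        with pytest.raises(ValidationError):
            arterial_resistance(90.0, 0.0)


class TestWindkessel:
    def make_cycle(self, rng=None, period=0.9, sv=80.0):
        rng = rng or np.random.default_rng(0)
        dt = 0.0096
        q = make_forward_wave(period, dt, sv, 0.33)
        n = q.size
        return AorticCycle(time=np.arange(n) * dt, area=np.full(n, 5.0), flow=q,
                           period=n * dt)

    def test_closed_form_matches_rk4_oracle(self):
        rng = np.random.default_rng(42)
        cyc = self.make_cycle()
        for _ in range(5):
            r = rng.uniform(10, 30)  # Woods units
            c = rng.uniform(0.4, 2.5)  # mL/mmHg
            p_closed = windkessel_pressure(cyc, r, c)
            t_o, p_o = wk2_oracle(cyc, r, c)
            p_oracle = np.interp(cyc.time, t_o, p_o)
            pp_c = p_closed.max() - p_closed.min()
            pp_o = float(p_o.max() - p_o.min())
            assert pp_c == pytest.approx(pp_o, rel=5e-3)
            assert np.max(np.abs(p_closed - p_oracle)) / np.mean(p_oracle) < 5e-3

    def test_recovers_known_compliance_from_oracle_pulse_pressure(self):
        rng = np.random.default_rng(9)
        cyc = self.make_cycle()
        for _ in range(5):
            r_true = rng.uniform(12, 25)
            c_true = rng.uniform(0.5, 2.0)
            _, p = wk2_oracle(cyc, r_true, c_true)
            pp = float(p.max() - p.min())
            c_hat = tac_windkessel(cyc, r_true, pp)
            assert c_hat == pytest.approx(c_true, rel=0.01)

    def test_model_pp_monotone_decreasing_in_c_increasing_in_r(self):
        cyc = self.make_cycle()
        cs = np.geomspace(0.2, 5.0, 12)
        pps = [np.ptp(windkessel_pressure(cyc, 18.0, c)) for c in cs]
        assert np.all(np.diff(pps) < 0)
        rs = np.linspace(8.0, 40.0, 10)
        pps_r = [np.ptp(windkessel_pressure(cyc, r, 1.0)) for r in rs]
        assert np.all(np.diff(pps_r) > 0)

    def test_constant_flow_unreachable(self):
        n = 64
        cyc = AorticCycle(time=np.arange(n) * 0.01, area=np.full(n, 5.0),
                          flow=np.full(n, 90.0))
        with pytest.raises(TuningError, match="unreachable"):
            tac_windkessel(cyc, 18.0, 40.0)

    def test_central_tac_at_least_brachial_when_central_pp_smaller(self):
        cyc = self.make_cycle()
        tac_c = tac_windkessel(cyc, 18.0, 38.0)  # central PP (smaller)
        tac_b = tac_windkessel(cyc, 18.0, 46.0)  # brachial PP
        assert tac_c >= tac_b


class TestMorphology:
    def test_study_median_coarctation_index(self):
        ti, ci, flag = morphology_indices(21.0, 18.2, 20.0)
        assert ci == pytest.approx(0.91)
        assert ti == pytest.approx(1.05)
        assert not flag

    def test_equal_diameters_and_threshold_flag(self):
        ti, ci, flag = morphology_indices(20.0, 20.0, 20.0)
        assert ti == ci == 1.0 and not flag
        _, ci2, flag2 = morphology_indices(20.0, 13.8, 20.0)
        assert ci2 == pytest.approx(0.69) and flag2

    def test_missing_diameters_yield_absent_indices(self):
        ti, ci, flag = morphology_indices(None, None, 20.0)
        assert ti is None and ci is None and not flag
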