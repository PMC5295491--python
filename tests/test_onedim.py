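"""Reduced 1-D aorta: scenario construction, physics and numerics.

Scenario simulations are cached at module scope (deterministic solver), so
the stiff case's cost is paid once per session.
"""

import numpy as np
import pytest
from dataclasses import replace

from coawave.errors import ValidationError
from coawave.onedim import (
    OneDSegment,
    ScenarioSpec,
    build_scenario,
    default_network,
    scenario_result,
    scenario_spec,
    scenario_wia,
    simulate,
    tube_wave_speed,
    uniform_tube_network,
)
from coawave.wave_intensity import analyze_cycle


class TestScenarioConstruction:
    def test_baseline_is_unmodified(self):
        net = default_network()
        assert build_scenario(scenario_spec("baseline"), net) == net

    def test_narrow_scales_target_diameters_exactly(self):
        net = default_network()
        spec = scenario_spec("narrow")
        mod = build_scenario(spec, net)
        seg0 = net.segments[spec.target_segment]
        seg1 = mod.segments[spec.target_segment]
        assert seg1.inlet_diameter / seg0.inlet_diameter == pytest.approx(0.75, rel=1e-12)
        assert seg1.outlet_diameter / seg0.outlet_diameter == pytest.approx(0.75, rel=1e-12)
        assert seg1.distensibility == seg0.distensibility

    def test_narrow_stiff_divides_distensibility_by_1e5(self):
        net = default_network()
        spec = scenario_spec("narrow_stiff")
        mod = build_scenario(spec, net)
        ratio = (
            mod.segments[spec.target_segment].distensibility
            / net.segments[spec.target_segment].distensibility
        )
        assert ratio == pytest.approx(1e-5, rel=1e-12)

    def test_segment_and_spec_validation(self):
        with pytest.raises(ValidationError):
            OneDSegment(4.0, 2.0, 2.0, 5e-3, n_nodes=4)
        with pytest.raises(ValidationError):
            ScenarioSpec(name="narrow", narrowing_fraction=0.95)
        with pytest.raises(ValidationError):
            scenario_spec("wide")


class TestScenarioPhysics:
    def test_root_pressure_is_control_like(self):
        res = scenario_result("baseline")
        assert res.converged
        assert 90 <= res.pressure.max() <= 130
        assert 50 <= res.pressure.min() <= 85

    def test_bcw_magnitude_ordering_across_scenarios(self):
        mags = {n: scenario_wia(n).bcw_magnitude for n in ("baseline", "narrow", "narrow_stiff")}
        assert mags["narrow_stiff"] > mags["narrow"] > mags["baseline"]

    def test_mass_balance_within_half_percent(self):
        for name in ("baseline", "narrow", "narrow_stiff"):
            res = scenario_result(name)
            assert res.mass_error < 0.005

    def test_stiff_bcw_arrives_no_later_than_baseline_backward_wave(self):
        stiff = scenario_wia("narrow_stiff")
        base = scenario_wia("baseline")
        stiff_bcw = max((w for w in stiff.waves if w.kind == "BCW"), key=lambda w: w.magnitude)
        base_back = [w for w in base.waves if w.kind == "BCW"]
        assert stiff_bcw.t_peak <= min(w.t_peak for w in base_back)

    def test_travel_time_consistency(self):
        """BCW onset delay from ejection onset ~ 2 x distance to the repair
        segment / wave speed, within 25%."""
        w = scenario_wia("narrow_stiff")
        fcw = next(x for x in w.waves if x.kind == "FCW")
        bcw = max((x for x in w.waves if x.kind == "BCW"), key=lambda x: x.magnitude)
        delay = bcw.t_onset - fcw.t_onset
        net = default_network()
        dist = sum(s.length for s in net.segments[:3]) / 100.0  # m to target inlet
        res = scenario_result("narrow_stiff")
        cyc = res.cycle
        dp = float(res.pressure.max() - res.pressure.min())
        from coawave.afterload import bramwell_hill_pwv

        c = bramwell_hill_pwv(cyc.diastolic_area, cyc.systolic_area - cyc.diastolic_area, dp)
        expected = 2.0 * dist / c
        assert delay == pytest.approx(expected, rel=0.25)


class TestNumerics:
    def test_matched_uniform_tube_is_reflectionless(self):
        net = uniform_tube_network(matched=True)
        res = simulate(net)
        w = analyze_cycle(res.cycle, tube_wave_speed(net))
        assert w.reflection_magnitude < 0.02

    def test_mismatched_tube_reflects(self):
        net = uniform_tube_network(matched=False)
        res = simulate(net)
        w = analyze_cycle(res.cycle, tube_wave_speed(net))
        assert w.reflection_magnitude > 0.2

    def test_grid_halving_changes_bcw_by_under_five_percent(self):
        net = default_network()
        fine = replace(net, segments=tuple(replace(s, n_nodes=2 * s.n_nodes) for s in net.segments))
        coarse_mag = scenario_wia("narrow").bcw_magnitude
        res = simulate(build_scenario(scenario_spec("narrow"), fine))
        cyc = res.cycle
        from coawave.afterload import bramwell_hill_pwv

        dp = float(res.pressure.max() - res.pressure.min())
        w = analyze_cycle(
            cyc, bramwell_hill_pwv(cyc.diastolic_area, cyc.systolic_area - cyc.diastolic_area, dp)
        )
        assert w.bcw_magnitude == pytest.approx(coarse_mag, rel=0.05)

    def test_simulation_is_deterministic(self):
        net = uniform_tube_network()
        r1 = simulate(net)
        r2 = simulate(net)
        np.testing.assert_array_equal(r1.cycle.area, r2.cycle.area)
        np.testing.assert_array_equal(r1.pressure, r2.pressure)
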