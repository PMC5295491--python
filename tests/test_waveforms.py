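"""Domain types, IO round-trip and preprocessing."""

import numpy as np
import pytest

from coawave.errors import ValidationError
from coawave.io import read_subject_csv, write_subject_csv
from coawave.waveforms import (
    AorticCycle,
    BrachialBP,
    SubjectRecord,
    increments,
    resample_uniform,
    smooth,
)

from conftest import simple_cycle


def make_record(cycle, **kw):
    return SubjectRecord(
        id=kw.get("id", "S1"),
        group=kw.get("group", "patient"),
        bsa=1.9,
        bp=BrachialBP(sbp=135.0, dbp=75.0, mbp=95.0),
        cycle=cycle,
        sex="F",
        age=31.0,
        lvm=kw.get("lvm"),
        diam_transverse=kw.get("diam_transverse"),
        diam_isthmus=kw.get("diam_isthmus"),
        diam_descending=kw.get("diam_descending"),
    )


class TestAorticCycle:
    def test_valid_construction_and_derived_views(self, cycle):
        assert cycle.dt == pytest.approx(0.0096)
        assert cycle.diastolic_area == pytest.approx(5.0)
        assert cycle.systolic_area > cycle.diastolic_area
        assert cycle.heart_rate == pytest.approx(60.0 / cycle.period)

    @pytest.mark.parametrize(
        "mutate, field",
        [
            (lambda t, a, q: (t, np.where(np.arange(a.size) == 3, 0.0, a), q), "area"),
            (lambda t, a, q: (t, -a, q), "area"),
            (lambda t, a, q: (t**1.5, a, q), "time"),
            (lambda t, a, q: (t + 0.1, a, q), "time"),
            (lambda t, a, q: (t[:8], a[:8], q[:8]), "time"),
            (lambda t, a, q: (t, np.where(np.arange(a.size) == 0, np.nan, a), q), "area"),
        ],
    )
    def test_invariant_violations_name_the_field(self, mutate, field):
        t = np.arange(50) * 0.01
        a = np.full(50, 5.0)
        q = np.zeros(50)
        with pytest.raises(ValidationError) as err:
            AorticCycle(*mutate(t, a, q))
        assert err.value.field == field

    def test_bp_ordering_enforced(self):
        with pytest.raises(ValidationError, match="BP ordering"):
            BrachialBP(sbp=140.0, dbp=80.0, mbp=75.0)
        with pytest.raises(ValidationError):
            BrachialBP(sbp=140.0, dbp=-1.0, mbp=90.0)


class TestIO:
    def test_round_trip_preserves_numeric_fields(self, tmp_path, cycle):
        rec = make_record(cycle, lvm=140.0, diam_transverse=21.0,
                          diam_isthmus=18.2, diam_descending=20.0)
        write_subject_csv(rec, tmp_path / "S1")
        back = read_subject_csv(tmp_path / "S1.csv")
        np.testing.assert_allclose(back.cycle.area, rec.cycle.area, atol=1e-9)
        np.testing.assert_allclose(back.cycle.flow, rec.cycle.flow, atol=1e-9)
        np.testing.assert_allclose(back.cycle.time, rec.cycle.time, atol=1e-9)
        assert back.cycle.period == pytest.approx(rec.cycle.period, abs=1e-9)
        for attr in ("bsa", "age", "lvm", "diam_isthmus"):
            assert getattr(back, attr) == pytest.approx(getattr(rec, attr), abs=1e-9)
        assert (back.id, back.group, back.sex) == ("S1", "patient", "F")
        assert back.bp == rec.bp

    def test_missing_column_and_bad_values_raise(self, tmp_path, cycle):
        rec = make_record(cycle)
        write_subject_csv(rec, tmp_path / "S2")
        csv = tmp_path / "S2.csv"
        text = csv.read_text().replace("flow_ml_s", "flow")
        csv.write_text(text)
        with pytest.raises(ValidationError, match="flow_ml_s"):
            read_subject_csv(csv)

    def test_nonpositive_area_raises_on_read(self, tmp_path, cycle):
        rec = make_record(cycle)
        write_subject_csv(rec, tmp_path / "S3")
        lines = (tmp_path / "S3.csv").read_text().splitlines()
        t, _, q = lines[1].split(",")
        lines[1] = ",".join([t, "0.0", q])
        (tmp_path / "S3.csv").write_text("\n".join(lines))
        with pytest.raises(ValidationError, match="non-positive area"):
            read_subject_csv(tmp_path / "S3.csv")


class TestPreprocessing:
    def test_resample_at_native_grid_is_identity(self, cycle):
        out = resample_uniform(cycle, cycle.dt)
        assert out is cycle

    def test_resample_linear_ramp_hits_exact_midpoints(self):
        n = 33
        t = np.arange(n) * 0.01
        area = 4.0 + 0.1 * t  # linear
        flow = 10.0 * t
        cyc = AorticCycle(time=t, area=area, flow=flow)
        out = resample_uniform(cyc, 0.005)
        np.testing.assert_allclose(out.area, 4.0 + 0.1 * out.time, rtol=1e-12)
        np.testing.assert_allclose(out.flow, 10.0 * out.time, rtol=1e-12)
        assert out.area[0] == cyc.area[0] and out.area[-1] == pytest.approx(cyc.area[-1])

    def test_resample_too_coarse_rejected(self, cycle):
        with pytest.raises(ValidationError, match="too coarse"):
            resample_uniform(cycle, cycle.period / 4)

    def test_smooth_reproduces_polynomials_up_to_order(self):
        t = np.arange(64) * 0.01
        quad = 5.0 + 3.0 * t + 2.0 * t**2
        cyc = AorticCycle(time=t, area=quad, flow=np.full(64, 7.0))
        out = smooth(cyc, window=11, polyorder=2)
        np.testing.assert_allclose(out.area, quad, atol=1e-10)
        np.testing.assert_allclose(out.flow, 7.0, atol=1e-10)

    def test_smooth_even_window_rejected(self, cycle):
        with pytest.raises(ValidationError, match="window"):
            smooth(cycle, window=4)

    def test_increments_arithmetic_and_telescoping(self):
        t = np.arange(16) * 0.01
        area = np.linspace(5.0, 5.15, 16)
        area[1], area[2] = 5.2, 5.1
        cyc = AorticCycle(time=t, area=area, flow=np.zeros(16))
        dA, dQ = increments(cyc)
        assert dA[0] == pytest.approx(0.2) and dA[1] == pytest.approx(-0.1)
        assert dA.size == 15 and np.all(dQ == 0)
        assert dA.sum() == pytest.approx(area[-1] - area[0], abs=1e-15)

    def test_increments_linearity(self, cycle):
        dA, dQ = increments(cycle)
        scaled = AorticCycle(
            time=cycle.time, area=3.0 * cycle.area, flow=3.0 * cycle.flow
        )
        dA3, dQ3 = increments(scaled)
        np.testing.assert_allclose(dA3, 3.0 * dA, rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(dQ3, 3.0 * dQ, rtol=1e-12, atol=1e-9)
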