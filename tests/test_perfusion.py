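"""Oxygen content, saturation curve and MVO2 against hand and brute-force oracles."""

import numpy as np
import pytest

from hypometrics import perfusion, synthio
from hypometrics.perfusion import PerfusionConstants
from hypometrics.types import BloodGasSample, InvalidArgumentError, MissingFieldError, PerfusionRecord

CONST_K3 = PerfusionConstants(k_table=((0.0, 0.003), (40.0, 0.003)))


class TestSeveringhaus:
    def test_zero_at_zero(self):
        assert perfusion.severinghaus_so2(0.0) == 0.0

    def test_approaches_one(self):
        assert perfusion.severinghaus_so2(1e4) > 0.999

    def test_half_saturation_point(self):
        # closed form evaluated numerically: P50 of the human curve
        assert perfusion.severinghaus_so2(26.86) == pytest.approx(0.500, abs=0.001)

    def test_strictly_increasing(self):
        p = np.linspace(0.0, 500.0, 2000)
        s = perfusion.severinghaus_so2(p)
        assert np.all(np.diff(s) > 0)

    def test_inverse_composes_to_identity(self):
        for p in np.linspace(1.0, 500.0, 50):
            s = perfusion.severinghaus_so2(p)
            assert perfusion.severinghaus_po2(s) == pytest.approx(p, abs=1e-6)

    def test_negative_po2_rejected(self):
        with pytest.raises(InvalidArgumentError):
            perfusion.severinghaus_so2(-1.0)


class TestO2Content:
    def test_zero_inputs(self):
        s = BloodGasSample("arterial", 0.0, 0.0, 0.0, 37.0)
        assert perfusion.o2_content(s, CONST_K3, "measured") == 0.0

    def test_hand_arithmetic_saturated(self):
        s = BloodGasSample("arterial", 400.0, 3.0, 1.0, 37.0)
        assert perfusion.o2_content(s, CONST_K3, "measured") == pytest.approx(5.22)

    def test_hand_arithmetic_half_saturated(self):
        s = BloodGasSample("venous", 50.0, 3.0, 0.5, 37.0)
        assert perfusion.o2_content(s, CONST_K3, "measured") == pytest.approx(2.16)

    def test_missing_so2_raises_in_measured_mode(self):
        s = BloodGasSample("venous", 50.0, 3.0, None, 37.0)
        with pytest.raises(MissingFieldError):
            perfusion.o2_content(s, CONST_K3, "measured")

    def test_k_table_decreasing_in_temperature(self):
        c = PerfusionConstants()
        ks = [c.k_solubility(t) for t in np.linspace(4.0, 40.0, 20)]
        assert all(a >= b for a, b in zip(ks, ks[1:]))
        assert c.k_solubility(4.0) == pytest.approx(0.00415)
        assert c.k_solubility(37.0) == pytest.approx(0.003, rel=0.05)


def _record(po2a, so2a, po2v, so2v, q, w, hb=3.0, temp=37.0):
    return PerfusionRecord(
        BloodGasSample("arterial", po2a, hb, so2a, temp),
        BloodGasSample("venous", po2v, hb, so2v, temp),
        q,
        w,
    )


class TestMvo2:
    def test_equal_contents_zero(self):
        rec = _record(100.0, 0.9, 100.0, 0.9, 200.0, 300.0)
        assert perfusion.compute_mvo2(rec, CONST_K3).value == 0.0

    def test_hand_arithmetic(self):
        # contents 5.22 and 2.16 mL/dL, Q=100, weight=300 -> 1.02
        rec = _record(400.0, 1.0, 50.0, 0.5, 100.0, 300.0)
        res = perfusion.compute_mvo2(rec, CONST_K3, "measured")
        assert res.value == pytest.approx(1.02)

    def test_generator_roundtrip(self):
        records, _ = synthio.gen_perfusion_records(true_mvo2=2.4, n_timepoints=3)
        for rec in records:
            for mode in ("measured", "computed"):
                assert perfusion.compute_mvo2(rec, so2_source=mode).value == pytest.approx(
                    2.4, rel=1e-9
                )

    def test_doubling_flow_and_weight_invariant(self):
        rec1 = _record(400.0, 1.0, 50.0, 0.5, 100.0, 300.0)
        rec2 = _record(400.0, 1.0, 50.0, 0.5, 200.0, 600.0)
        a = perfusion.compute_mvo2(rec1, CONST_K3, "measured").value
        b = perfusion.compute_mvo2(rec2, CONST_K3, "measured").value
        assert a == pytest.approx(b, rel=1e-12)

    def test_negative_mvo2_warned_not_raised(self):
        rec = _record(50.0, 0.5, 400.0, 1.0, 100.0, 300.0)
        res = perfusion.compute_mvo2(rec, CONST_K3, "measured")
        assert res.value < 0
        assert any("negative" in w for w in res.warnings)

    def test_brute_force_oracle_on_random_records(self, rng):
        """Stepwise arithmetic re-derivation agrees to 1e-12 relative."""
        constants = PerfusionConstants()
        for _ in range(300):
            po2a = rng.uniform(100.0, 600.0)
            po2v = rng.uniform(5.0, po2a)
            hb = rng.uniform(1.0, 15.0)
            q = rng.uniform(50.0, 1000.0)
            w = rng.uniform(100.0, 600.0)
            temp = rng.uniform(4.0, 40.0)
            rec = PerfusionRecord(
                BloodGasSample("arterial", po2a, hb, None, temp),
                BloodGasSample("venous", po2v, hb, None, temp),
                q,
                w,
            )
            res = perfusion.compute_mvo2(rec, constants, "computed")
            # independent stepwise oracle
            k = float(np.interp(temp, [r[0] for r in constants.k_table], [r[1] for r in constants.k_table]))
            sat = lambda p: 1.0 / (23400.0 / (p * p * p + 150.0 * p) + 1.0)  # noqa: E731
            ca = 1.34 * hb * sat(po2a) + k * po2a
            cv = 1.34 * hb * sat(po2v) + k * po2v
            expected = ((ca - cv) / 100.0 * q / w) * 100.0
            assert res.value == pytest.approx(expected, rel=1e-12)


class TestTimecourse:
    def test_constant_records_constant_series(self):
        records, _ = synthio.gen_perfusion_records(true_mvo2=1.5, n_timepoints=4)
        tab = perfusion.mvo2_timecourse(records)
        assert np.allclose(tab["value"], 1.5)
        assert list(tab["timepoint"]) == [0.0, 1.0, 2.0, 3.0]

    def test_two_phase_step(self):
        r1, _ = synthio.gen_perfusion_records(true_mvo2=4.0, n_timepoints=2)
        r2, _ = synthio.gen_perfusion_records(true_mvo2=2.0, n_timepoints=2)
        for i, rec in enumerate(r1 + r2):
            rec.time = float(i)
        tab = perfusion.mvo2_timecourse(r1 + r2)
        assert np.allclose(tab["value"], [4.0, 4.0, 2.0, 2.0])

    def test_empty_input_empty_table(self):
        assert len(perfusion.mvo2_timecourse([])) == 0

    def test_provenance_recorded(self):
        records, _ = synthio.gen_perfusion_records(true_mvo2=1.0, n_timepoints=1)
        tab = perfusion.mvo2_timecourse(records)
        assert "K=" in tab["provenance"].iloc[0]
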