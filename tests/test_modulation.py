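"""AEC noise-index model, ODM/TCM multipliers and patient-log analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odmsim.modulation import (
    MedianModulationTable,
    aec_dose_for_noise_index,
    build_profile,
    match_ctdivol_rescale,
    median_modulation_table,
    noise_index_to_match_dose,
    normalize_patient_currents,
    odm_multiplier,
    quadrant_class_of,
    tcm_multiplier,
)
from odmsim.synthetic import gen_patient_ma_logs

ANGLES = np.arange(0.0, 360.0, 10.0)


class TestNoiseIndexModel:
    def test_reference_point_is_identity(self):
        assert aec_dose_for_noise_index(10, 10, 8.18) == pytest.approx(8.18)

    def test_inverse_square_scaling_matches_scanner_table(self):
        # doubling NI quarters the dose: 8.18 -> 2.045, close to the
        # scanner-displayed 2.08 at NI 20
        d = aec_dose_for_noise_index(20, 10, 8.18, base_ma_at_ref=200)
        assert d == pytest.approx(8.18 / 4, rel=1e-12)
        assert d == pytest.approx(2.08, abs=0.05)

    def test_ma_floor_dominates_at_high_noise_index(self):
        # with a 120 mA baseline, NI 40 implies 7.5 mA -> clamped to 10 mA,
        # so the delivered dose exceeds the inverse-square prediction
        d = aec_dose_for_noise_index(40, 10, 8.18, min_ma=10, base_ma_at_ref=120)
        assert d == pytest.approx(8.18 * 10 / 120)
        assert d > 8.18 / 16

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            aec_dose_for_noise_index(-1, 10, 8.18)
        with pytest.raises(ValueError):
            noise_index_to_match_dose(10, 8.18, 0.0)

    def test_matched_ctdivol_noise_indexes(self):
        """The worked examples from the scanner's matched-CTDIvol settings."""
        assert noise_index_to_match_dose(10, 8.18, 8.18) == pytest.approx(10.0)
        assert noise_index_to_match_dose(10, 8.18, 6.57) == pytest.approx(11.16, abs=0.01)
        assert noise_index_to_match_dose(10, 6.56, 8.19) == pytest.approx(8.95, abs=0.01)


class TestOdmMultiplier:
    def test_anterior_and_posterior_values(self):
        assert odm_multiplier(0.0) == pytest.approx(0.6)
        assert odm_multiplier(180.0) == pytest.approx(1.0)
        assert odm_multiplier(0.0, arc_deg=180, reduction=0.4) == pytest.approx(0.6)

    def test_boundary_sector_average(self):
        assert odm_multiplier(90.0, sector_deg=10.0) == pytest.approx(0.8)
        assert odm_multiplier(-90.0, sector_deg=10.0) == pytest.approx(0.8)
        m = np.array([odm_multiplier(t, sector_deg=10.0) for t in ANGLES])
        assert m.mean() == pytest.approx(0.8, abs=1e-12)

    @given(
        arc=st.floats(30, 360),
        reduction=st.floats(0, 0.9),
        n=st.sampled_from([12, 36, 90]),
    )
    @settings(max_examples=25, deadline=None)
    def test_rotation_mean_equals_arc_fraction(self, arc, reduction, n):
        """Sector-averaged multipliers preserve 1 - r*A/360 on any grid."""
        angles = np.arange(n) * 360.0 / n
        m = np.array([odm_multiplier(t, arc, reduction, sector_deg=360.0 / n) for t in angles])
        assert m.mean() == pytest.approx(1 - reduction * arc / 360.0, abs=1e-9)

    def test_sector_average_brute_force_oracle(self):
        # fine sub-sampling of each 10-degree sector must agree with the
        # analytic overlap computation
        for theta in (85.0, 90.0, 95.0, 270.0, 0.0):
            fine = np.linspace(theta - 5, theta + 5, 20001)
            oracle = np.mean([odm_multiplier(t) for t in fine])
            assert odm_multiplier(theta, sector_deg=10.0) == pytest.approx(oracle, abs=1e-3)


class TestTcmMultiplier:
    def test_identity_table(self):
        t = MedianModulationTable.identity()
        for theta in (0, 45, 90, 200):
            assert tcm_multiplier(300.0, theta, t) == 1.0

    def test_lookup_by_region_and_quadrant(self):
        values = {(r, q): dict(median=1.0, iqr_low=1, iqr_high=1)
                  for r in ("chest", "abdomen", "pelvis") for q in ("AP", "lateral")}
        values[("chest", "AP")]["median"] = 0.7
        t = MedianModulationTable(values)
        assert tcm_multiplier(600.0, 0.0, t) == pytest.approx(0.7)
        assert tcm_multiplier(600.0, 90.0, t) == pytest.approx(1.0)
        assert tcm_multiplier(100.0, 0.0, t) == pytest.approx(1.0)

    def test_rotation_mean_is_average_of_quadrant_medians(self):
        t = MedianModulationTable.default()
        for z in (100.0, 300.0, 600.0):
            m = np.array([tcm_multiplier(z, theta, t) for theta in ANGLES])
            region = {100.0: "pelvis", 300.0: "abdomen", 600.0: "chest"}[z]
            expected = 0.5 * (t.median(region, "AP") + t.median(region, "lateral"))
            assert m.mean() == pytest.approx(expected, rel=1e-12)

    def test_missing_entry_rejected(self):
        t = MedianModulationTable({("chest", "AP"): dict(median=1, iqr_low=1, iqr_high=1)})
        with pytest.raises(KeyError):
            tcm_multiplier(600.0, 90.0, t)

    def test_quadrant_boundaries(self):
        assert quadrant_class_of(44.9) == "AP"
        assert quadrant_class_of(45.0) == "lateral"
        assert quadrant_class_of(135.0) == "AP"
        assert quadrant_class_of(315.0) == "lateral"


class TestProfiles:
    def test_odm_profile_rotation_mean(self):
        prof = build_profile(np.array([0.0]), ANGLES, odm=True)
        assert prof.rotation_mean()[0] == pytest.approx(0.8)

    def test_matched_rescale_restores_mean(self):
        prof = build_profile(np.array([0.0]), ANGLES, odm=True)
        scaled = match_ctdivol_rescale(prof, 1.25)
        assert scaled.rotation_mean()[0] == pytest.approx(1.0)
        assert scaled.multipliers[0, 0] == pytest.approx(0.75)
        assert scaled.multipliers[0, 18] == pytest.approx(1.25)

    def test_rescale_identity_and_errors(self):
        prof = build_profile(np.array([0.0]), ANGLES, odm=True)
        same = match_ctdivol_rescale(prof, 1.0)
        np.testing.assert_array_equal(same.multipliers, prof.multipliers)
        with pytest.raises(ValueError):
            match_ctdivol_rescale(prof, -1.0)
        with pytest.warns(UserWarning, match="max_ma"):
            match_ctdivol_rescale(prof, 10.0)

    def test_composition_commutes(self):
        """TCM x ODM x rescale is a pure product: order cannot matter."""
        z = np.arange(11.5, 700, 23.0)
        t = MedianModulationTable.default()
        a = build_profile(z, ANGLES, odm=True, tcm_table=t, rescale=1.25)
        odm_only = build_profile(z, ANGLES, odm=True)
        tcm_only = build_profile(z, ANGLES, odm=False, tcm_table=t)
        np.testing.assert_allclose(
            a.multipliers, 1.25 * odm_only.multipliers * tcm_only.multipliers, atol=1e-12
        )

    def test_clamping_idempotent(self):
        prof = build_profile(np.array([0.0]), ANGLES, odm=True, base_ma=20.0)
        c1 = prof.clamped()
        from dataclasses import replace

        prof2 = replace(prof, multipliers=c1)
        np.testing.assert_allclose(prof2.clamped(), c1)

    def test_posterior_compensation_conserves_rotation_mean(self):
        prof = build_profile(np.array([0.0]), ANGLES, odm=True, compensate_posterior=True)
        assert prof.rotation_mean()[0] == pytest.approx(1.0, abs=1e-9)
        assert prof.multipliers[0, 0] == pytest.approx(0.6)
        assert prof.multipliers[0, 18] > 1.0


class TestPatientCurrents:
    def test_single_record_normalizes_to_one(self):
        df = pd.DataFrame(
            [dict(patient_id=1, z_mm=100.0, quadrant_class="AP", ma=250.0)]
        )
        out = normalize_patient_currents(df)
        assert out["norm_ma"].iloc[0] == 1.0

    def test_two_record_arithmetic(self):
        df = pd.DataFrame(
            [
                dict(patient_id=1, z_mm=100.0, quadrant_class="AP", ma=100.0),
                dict(patient_id=1, z_mm=600.0, quadrant_class="AP", ma=300.0),
            ]
        )
        out = normalize_patient_currents(df)
        np.testing.assert_allclose(out["norm_ma"], [0.5, 1.5])

    def test_generated_logs_roundtrip_to_unit_means(self):
        logs = gen_patient_ma_logs(seed=5)
        out = normalize_patient_currents(logs)
        means = out.groupby("patient_id")["norm_ma"].mean()
        np.testing.assert_allclose(means, 1.0, atol=1e-12)

    def test_nonpositive_ma_rejected(self):
        df = pd.DataFrame(
            [dict(patient_id=1, z_mm=100.0, quadrant_class="AP", ma=0.0)]
        )
        with pytest.raises(ValueError):
            normalize_patient_currents(df)


class TestMedianModulationTable:
    def test_constant_input_gives_unit_medians(self):
        rows = []
        for z, qc in [(100, "AP"), (100, "lateral"), (300, "AP"), (300, "lateral"),
                      (600, "AP"), (600, "lateral")]:
            rows.append(dict(patient_id=1, z_mm=float(z), quadrant_class=qc, ma=200.0))
        table = median_modulation_table(normalize_patient_currents(pd.DataFrame(rows)))
        for key, v in table.values.items():
            assert v["median"] == pytest.approx(1.0)
            assert v["iqr_high"] - v["iqr_low"] == pytest.approx(0.0)

    def test_patient_order_invariance(self):
        logs = gen_patient_ma_logs(seed=9)
        shuffled = logs.sample(frac=1.0, random_state=0).reset_index(drop=True)
        t1 = median_modulation_table(normalize_patient_currents(logs))
        t2 = median_modulation_table(normalize_patient_currents(shuffled))
        for key in t1.values:
            assert t1.values[key]["median"] == pytest.approx(t2.values[key]["median"])

    def test_empty_category_rejected(self):
        df = pd.DataFrame(
            [dict(patient_id=1, z_mm=100.0, quadrant_class="AP", ma=100.0)]
        )
        with pytest.raises(ValueError, match="no records"):
            median_modulation_table(normalize_patient_currents(df))
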