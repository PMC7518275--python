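"""HU definition, calibration-referenced correction and change predictions."""

import numpy as np
import pytest

from hucorr import (
    BeamModelParams,
    DepthQuery,
    MaterialTable,
    ScannerCalibration,
    build_phantom_spec,
    correct_measured_hu,
    corrected_hu,
    effective_energy,
    hu_from_mu,
    interpolate_mu_water,
    predict_delta_hu_depth,
    predict_delta_hu_size,
)

KVPS = (80.0, 110.0, 130.0)
SOLIDS = ("breast", "adipose", "liver", "muscle", "bone200", "bone800", "bone1250")


class TestEffectiveEnergy:
    @pytest.mark.parametrize("kvp,kev", [(80, 58), (110, 64), (130, 72)])
    def test_mapped_voltages(self, calib, kvp, kev):
        assert effective_energy(kvp, calib) == kev

    def test_linear_interpolation_between_keys(self, calib):
        assert effective_energy(95, calib) == pytest.approx(61.0)

    def test_out_of_range_rejected(self, calib):
        with pytest.raises(ValueError, match="outside calibrated range"):
            effective_energy(140, calib)

    def test_calibration_invariants(self):
        with pytest.raises(ValueError, match="cal_kvp"):
            ScannerCalibration(cal_kvp=100.0)
        with pytest.raises(ValueError, match="strictly increasing"):
            ScannerCalibration(effective_energy_map=((80, 58), (110, 57), (130, 72)), cal_kvp=110)


class TestHuDefinition:
    def test_water_zero_double_thousand_air(self):
        assert hu_from_mu(0.2, 0.2) == 0.0
        assert hu_from_mu(0.4, 0.2) == pytest.approx(1000.0)
        assert hu_from_mu(0.0, 0.2) == pytest.approx(-1000.0)

    def test_nonpositive_water_reference_rejected(self):
        with pytest.raises(ValueError):
            hu_from_mu(0.2, 0.0)


class TestCorrectedHu:
    def test_reduces_to_plain_hu_when_correction_vanishes(self, zero_calib, params, wide_table):
        # x = r = 0 with a zero-size calibration: f_c terms are exactly zero
        mu_w = interpolate_mu_water(wide_table, 64.0)
        for m in (0.5, 1.0, 2.0):
            hu = corrected_hu(m * mu_w, DepthQuery(0.0, 0.0, 64.0), zero_calib, params, wide_table)
            assert hu == pytest.approx(hu_from_mu(m * mu_w, mu_w), abs=1e-12)

    def test_water_anchored_at_calibration_geometry(self, calib, params, wide_table):
        v = effective_energy(calib.cal_kvp, calib)
        mu_w = interpolate_mu_water(wide_table, v)
        hu = corrected_hu(mu_w, DepthQuery(15.0, 15.0, v), calib, params, wide_table)
        assert abs(hu) < 1e-9

    def test_hand_composition_oracle_zero_size_calibration(self, zero_calib, params, wide_table):
        # independent arithmetic: compose the correction factor into the HU
        # ratio with raw floats for a bone-like material at x = r = 9, 80 kVp
        v = 58.0
        mu_w = interpolate_mu_water(wide_table, v)
        sig = np.exp(np.interp(np.log(v), np.log(wide_table.energy_grid), np.log(wide_table.rayleigh)))
        x0 = 1.0 / sig
        eps = zero_calib.epsilon_system
        amp = 27.696 * v**-0.856
        fc9 = amp / (eps * x0 + 1.144) - amp / (eps * (x0 + 9.0) + 1.144)
        expected = 1000.0 * (2 * mu_w - mu_w + fc9) / (mu_w - fc9)
        got = corrected_hu(2 * mu_w, DepthQuery(9.0, 9.0, v), zero_calib, params, wide_table)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_overcorrection_raises(self, zero_calib, wide_table):
        # an absurdly large Rayleigh amplitude drives the denominator negative
        big = BeamModelParams(A=27696.0)
        with pytest.raises(ValueError, match="exceeds water attenuation"):
            corrected_hu(0.2, DepthQuery(30.0, 30.0, 64.0), zero_calib, big, wide_table)


class TestInverseCorrection:
    def test_round_trip_recovers_plain_hu(self, calib, params, wide_table, rng):
        worst = 0.0
        for _ in range(1000):
            v = rng.uniform(52.0, 95.0)
            mu_w = interpolate_mu_water(wide_table, v)
            mu = rng.uniform(0.3, 2.5) * mu_w
            q = DepthQuery(rng.uniform(0, 16.5), rng.uniform(0, 16.5), v)
            hu_meas = corrected_hu(mu, q, calib, params, wide_table)
            back = correct_measured_hu(hu_meas, q, calib, params, wide_table)
            worst = max(worst, abs(back - hu_from_mu(mu, mu_w)))
        assert worst < 1e-6

    def test_water_at_calibration_maps_to_zero(self, calib, params, wide_table):
        q = DepthQuery(15.0, 15.0, 64.0)
        assert correct_measured_hu(0.0, q, calib, params, wide_table) == pytest.approx(0.0, abs=1e-9)

    def test_rejects_hu_at_or_below_air(self, calib, params, wide_table):
        with pytest.raises(ValueError, match="-1000"):
            correct_measured_hu(-1000.0, DepthQuery(5, 9, 64.0), calib, params, wide_table)


class TestSizePrediction:
    def test_no_change_for_equal_sizes(self, calib, params, wide_table, materials):
        for m in ("water",) + SOLIDS:
            d = predict_delta_hu_size(m, 110, 24.0, 24.0, calib, params, wide_table, materials)
            assert d == 0.0

    def test_water_anchor_at_calibration(self, calib, params, wide_table, materials):
        d = predict_delta_hu_size("water", 110, 30.0, 30.0, calib, params, wide_table, materials)
        assert d == 0.0

    def test_antisymmetric_under_size_swap(self, calib, params, wide_table, materials):
        a = predict_delta_hu_size("bone800", 80, 18.0, 30.0, calib, params, wide_table, materials)
        b = predict_delta_hu_size("bone800", 80, 30.0, 18.0, calib, params, wide_table, materials)
        assert a == -b
        assert a != 0.0

    def test_table_matches_per_cell_composition(self, calib, params, wide_table, materials):
        for m in SOLIDS:
            for kvp in KVPS:
                v = effective_energy(kvp, calib)
                mu = materials.mu(m, v, wide_table)
                expected = corrected_hu(mu, DepthQuery(15.0, 15.0, v), calib, params, wide_table) - corrected_hu(
                    mu, DepthQuery(9.0, 9.0, v), calib, params, wide_table
                )
                got = predict_delta_hu_size(m, kvp, 18.0, 30.0, calib, params, wide_table, materials)
                assert got == pytest.approx(expected, rel=1e-12)

    def test_magnitude_ordering_follows_material_hu(self, calib, params, wide_table, materials):
        # |delta| grows with the material's nominal |HU|; bone1250 dominates
        deltas = {
            m: abs(predict_delta_hu_size(m, 80, 18.0, 30.0, calib, params, wide_table, materials))
            for m in SOLIDS
        }
        assert max(deltas, key=deltas.get) == "bone1250"
        assert deltas["bone1250"] > deltas["bone800"] > deltas["bone200"]

    def test_hardening_weakens_at_higher_voltage(self, calib, params, wide_table, materials):
        for m in SOLIDS:
            mags = [
                abs(predict_delta_hu_size(m, kvp, 18.0, 30.0, calib, params, wide_table, materials))
                for kvp in KVPS
            ]
            assert mags[0] > mags[1] > mags[2]

    def test_unknown_material_lists_known_names(self, calib, params, wide_table, materials):
        with pytest.raises(ValueError, match="bone1250"):
            predict_delta_hu_size("steel", 80, 18.0, 30.0, calib, params, wide_table, materials)


class TestDepthPrediction:
    def test_no_change_for_equal_depths(self, calib, params, wide_table, materials):
        d = predict_delta_hu_depth("muscle", 110, 5.0, 5.0, 30.0, calib, params, wide_table, materials)
        assert d == 0.0

    def test_depth_outside_body_rejected(self, calib, params, wide_table, materials):
        with pytest.raises(ValueError, match="outside the body"):
            predict_delta_hu_depth("muscle", 110, 5.0, 31.0, 30.0, calib, params, wide_table, materials)

    def test_table_matches_per_cell_composition(self, calib, params, wide_table, materials):
        for m in SOLIDS:
            for kvp in KVPS:
                v = effective_energy(kvp, calib)
                mu = materials.mu(m, v, wide_table)
                expected = corrected_hu(mu, DepthQuery(5.0, 15.0, v), calib, params, wide_table) - corrected_hu(
                    mu, DepthQuery(11.0, 15.0, v), calib, params, wide_table
                )
                got = predict_delta_hu_depth(m, kvp, 11.0, 5.0, 30.0, calib, params, wide_table, materials)
                assert got == pytest.approx(expected, rel=1e-12)

    def test_size_dominates_depth_at_experiment_geometry(self, calib, params, wide_table, materials):
        # insert at the hole-6 position: 3.5 cm deep in the head phantom,
        # 11 cm deep in the abdomen; hole 14 sits 6 cm outboard at 5 cm depth
        head = build_phantom_spec("head")
        abdomen = build_phantom_spec("abdomen")
        d6_head, d6_abd = head.depth_of_hole(6), abdomen.depth_of_hole(6)
        d14 = abdomen.depth_of_hole(14)
        for m in SOLIDS:
            for kvp in KVPS:
                size = predict_delta_hu_size(
                    m, kvp, 18.0, 30.0, calib, params, wide_table, materials,
                    depth1=d6_head, depth2=d6_abd,
                )
                depth = predict_delta_hu_depth(
                    m, kvp, d6_abd, d14, 30.0, calib, params, wide_table, materials
                )
                assert abs(size) > abs(depth)


class TestMaterialTable:
    def test_water_row_consistent_with_xsection_table(self, materials, wide_table):
        for v in (58.0, 64.0, 72.0):
            mu = materials.mu("water", v, wide_table)
            ref = interpolate_mu_water(wide_table, v)
            assert abs(mu - ref) / ref < 0.01

    def test_nominal_hu_round_trip(self, materials, wide_table):
        assert materials.hu_at("bone200", 64.0, wide_table) == pytest.approx(200.0, abs=1e-9)

    def test_csv_mu_schema_water_validation(self, tmp_path, wide_table):
        bad = tmp_path / "mats.csv"
        bad.write_text("material,energy_keV,mu_per_cm\nwater,64,0.3\n")
        with pytest.raises(ValueError, match="1%"):
            MaterialTable.from_csv(bad, wide_table)

    def test_csv_nominal_schema(self, tmp_path, wide_table):
        f = tmp_path / "mats.csv"
        f.write_text("material,nominal_hu\nwater,0\nfoo,123\n")
        t = MaterialTable.from_csv(f)
        assert t.hu_at("foo", 64.0, wide_table) == pytest.approx(123.0)
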