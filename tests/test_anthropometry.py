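"""Blood-volume/plasma-volume submodel and allometric clearance scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hptsim import (
    ModelParameters,
    PatientProfile,
    Sex,
    blood_volume,
    ideal_body_weight,
    pct_deviation_ibw,
    personalize,
    plasma_volume_raw,
    plasma_volume_scaled,
    reference_plasma_volume,
    t3_clearance_scaled,
    tsh_distribution_volume,
    volume_set,
)


class TestPatientProfile:
    def test_bmi_is_weight_over_height_squared(self):
        p = PatientProfile("male", 1.80, 81.0)
        assert p.bmi == 81.0 / 1.80**2

    @pytest.mark.parametrize("sex,expected", [("male", 0.45), ("female", 0.40)])
    def test_hematocrit_defaults_by_sex(self, sex, expected):
        assert PatientProfile(sex, 1.7, 70.0).hematocrit == expected

    def test_hematocrit_override_and_validation(self):
        assert PatientProfile("f", 1.7, 70.0, hematocrit=0.38).hematocrit == 0.38
        with pytest.raises(ValueError):
            PatientProfile("f", 1.7, 70.0, hematocrit=1.2)

    def test_sex_parsing_case_insensitive(self):
        assert PatientProfile("M", 1.7, 70.0).sex is Sex.MALE

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            PatientProfile("m", -1.7, 70.0)
        with pytest.raises(ValueError):
            PatientProfile("m", 1.7, 0.0)


class TestIdealWeight:
    @pytest.mark.parametrize(
        "height,sex,expected",
        [(1.76, "male", 77.67), (1.67, "female", 62.55), (1.70, "male", 71.50)],
    )
    def test_known_values(self, height, sex, expected):
        assert ideal_body_weight(height, sex) == pytest.approx(expected, abs=0.01)

    def test_nonpositive_height_rejected(self):
        with pytest.raises(ValueError):
            ideal_body_weight(0.0, "male")

    def test_extreme_height_warns(self):
        with pytest.warns(UserWarning):
            ideal_body_weight(1.0, "female")


class TestDeviationAndBloodVolume:
    def test_zero_deviation_at_ideal_weight(self):
        ibw = ideal_body_weight(1.7, "male")
        assert pct_deviation_ibw(ibw, 1.7, "male") == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "weight,height,sex,expected",
        [(63.0, 1.67, "female", 0.72), (67.53, 1.76, "male", -13.05)],
    )
    def test_known_deviations(self, weight, height, sex, expected):
        assert pct_deviation_ibw(weight, height, sex) == pytest.approx(expected, abs=0.01)

    def test_blood_volume_at_ideal_weight(self):
        # 63 kg exactly at ideal weight: per-kg volume 1.27 * 100^-0.627 L/kg
        v = 1.27 * 100.0 ** (-0.627) * 63.0
        assert v == pytest.approx(4.458, abs=0.001)

    def test_known_blood_and_plasma_volumes(self):
        assert blood_volume(63.0, 1.67, "female") == pytest.approx(4.438, abs=0.001)
        assert plasma_volume_raw(63.0, 1.67, "female", 0.40) == pytest.approx(2.659, abs=0.005)
        assert plasma_volume_raw(67.53, 1.76, "male", 0.45) == pytest.approx(2.868, abs=0.005)

    def test_plasma_volume_vanishes_as_hematocrit_to_one(self):
        v = plasma_volume_raw(63.0, 1.67, "female", 1.0 - 1e-9)
        assert v == pytest.approx(0.0, abs=1e-6)

    def test_invalid_hematocrit_rejected(self):
        with pytest.raises(ValueError):
            plasma_volume_raw(63.0, 1.67, "female", 0.0)

    @given(st.floats(min_value=-39.0, max_value=99.0), st.floats(min_value=0.5, max_value=30.0))
    @settings(max_examples=50, deadline=None)
    def test_per_kg_volume_strictly_decreasing_in_deviation(self, dev, delta):
        per_kg = lambda d: 1.27 * (100.0 + d) ** (0.373 - 1.0)
        assert per_kg(dev + delta) < per_kg(dev)

    @given(
        st.floats(min_value=40.0, max_value=140.0),
        st.floats(min_value=1.45, max_value=2.0),
        st.sampled_from(["male", "female"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_plasma_volume_increases_with_weight_and_height(self, weight, height, sex):
        eps_w, eps_h = 1.0, 0.02
        base = plasma_volume_raw(weight, height, sex)
        assert plasma_volume_raw(weight + eps_w, height, sex) > base
        assert plasma_volume_raw(weight, height + eps_h, sex) > base


class TestReferenceScaling:
    def test_reference_plasma_volume(self, params):
        assert reference_plasma_volume(params) == pytest.approx(2.77, abs=0.01)

    def test_scaled_volume_of_reference_female(self, params):
        pat = PatientProfile.from_bmi("female", params.H_Fref, params.BMI_Fref)
        assert plasma_volume_scaled(pat, params) == pytest.approx(3.09, abs=0.01)

    def test_mean_scaled_volume_over_references_is_exactly_base(self, params):
        vals = [
            plasma_volume_scaled(PatientProfile.from_bmi(s, h, b), params)
            for s, h, b in [
                ("male", params.H_Mref, params.BMI_Mref),
                ("female", params.H_Fref, params.BMI_Fref),
            ]
        ]
        assert np.mean(vals) == pytest.approx(3.2, abs=1e-12)

    def test_reference_volume_moves_with_female_reference_bmi(self, params):
        lo = reference_plasma_volume(params.replace(BMI_Fref=22.0))
        mid = reference_plasma_volume(params)
        hi = reference_plasma_volume(params.replace(BMI_Fref=24.0))
        assert lo < mid < hi


class TestTshVolumeAndClearance:
    @pytest.mark.parametrize("vp,expected", [(3.2, 5.2), (3.09, 5.09), (4.0, 6.0)])
    def test_tsh_volume_shift(self, vp, expected):
        assert tsh_distribution_volume(vp) == pytest.approx(expected, abs=1e-12)

    def test_tsh_volume_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            tsh_distribution_volume(0.0)

    def test_k05_scaling_known_values(self, params):
        f_ref = PatientProfile.from_bmi("female", params.H_Fref, params.BMI_Fref)
        m_ref = PatientProfile.from_bmi("male", params.H_Mref, params.BMI_Mref)
        assert t3_clearance_scaled(f_ref, params) == pytest.approx(0.185, abs=1e-12)
        assert t3_clearance_scaled(m_ref, params) == pytest.approx(0.194, abs=0.001)
        f_double = PatientProfile("female", f_ref.height, 2 * f_ref.weight)
        assert t3_clearance_scaled(f_double, params) == pytest.approx(0.3111, abs=0.0005)

    @given(factor=st.floats(min_value=0.5, max_value=3.0))
    @settings(max_examples=25, deadline=None)
    def test_k05_scaling_homogeneous(self, params, factor):
        """Doubling both the weight and reference weight leaves the rate unchanged."""
        pat = PatientProfile("female", 1.67, params.BMI_Fref * 1.67**2 * factor)
        scaled_ref = params.replace(BMI_Fref=params.BMI_Fref * factor)
        assert t3_clearance_scaled(pat, scaled_ref) == pytest.approx(params.k05, rel=1e-9)

    def test_volume_set_consistency(self, params, ref_female):
        vs = volume_set(ref_female, params)
        assert vs.v_p == pytest.approx(vs.v_b * (1 - ref_female.hematocrit), rel=1e-12)
        assert vs.v_tsh_new == pytest.approx(5.2 + vs.v_p_new - 3.2, rel=1e-12)
        assert vs.v_tsh_new > 2.0


class TestPersonalize:
    def test_reference_female_substitutions(self, params):
        pat = PatientProfile.from_bmi("female", params.H_Fref, params.BMI_Fref)
        pers = personalize(params, pat)
        assert pers.Vp == pytest.approx(3.09, abs=0.01)
        assert pers.VTSH == pytest.approx(5.09, abs=0.01)
        assert pers.k05 == pytest.approx(0.185, abs=1e-9)
        # everything else untouched
        assert pers.S4 == params.S4 and pers.B0 == params.B0

    def test_male_female_same_size_differ(self, params):
        m = personalize(params, PatientProfile("male", 1.70, 70.0))
        f = personalize(params, PatientProfile("female", 1.70, 70.0))
        assert m.Vp != f.Vp
        assert m.k05 != f.k05
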