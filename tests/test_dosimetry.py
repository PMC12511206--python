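"""Per-patient dose equations: worked examples, invariants, error contracts."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from petctdose import dosimetry as dm
from petctdose.errors import ConfigurationError, InvalidInputError


class TestReferenceModelAssignment:
    @pytest.mark.parametrize(
        "weight, name, coefficient",
        [
            (73.0, "70 kg adult", 0.019),
            (45.0, "57 kg adult", 0.024),  # inclusive lower edge
            (65.0, "57 kg adult", 0.024),  # inclusive upper edge
            (65.1, "70 kg adult", 0.019),
            (44.0, "33 kg child", 0.036),
            (44.999, "33 kg child", 0.036),
        ],
    )
    def test_weight_bands(self, weight, name, coefficient):
        entry = dm.assign_reference_model(weight)
        assert (entry.name, entry.coefficient) == (name, coefficient)

    @pytest.mark.parametrize("weight", [0.0, -5.0, math.nan, math.inf])
    def test_invalid_weight_rejected(self, weight):
        with pytest.raises(InvalidInputError):
            dm.assign_reference_model(weight)

    @given(st.floats(min_value=1e-3, max_value=500.0, allow_nan=False))
    def test_assignment_is_a_partition(self, weight):
        """Every positive weight matches exactly one entry of the default scheme."""
        scheme = dm.default_scheme()
        matches = [e for e in scheme.entries if e.matches(weight)]
        # entries are nested bands tried top-down: the first match is the answer,
        # and a true partition means stripping higher bands leaves exactly one.
        assert dm.assign_reference_model(weight, scheme) is matches[0]
        # make the nested bands disjoint (each band ends where the previous starts)
        # and check the weight falls in exactly one of them
        inside = []
        prev_lower = math.inf
        for e in scheme.entries:
            lo_ok = weight >= e.lower_bound if e.lower_inclusive else weight > e.lower_bound
            hi_ok = (
                weight < prev_lower
                if prev_inclusive
                else weight <= prev_lower
            ) if math.isfinite(prev_lower) else True
            inside.append(lo_ok and hi_ok)
            prev_lower, prev_inclusive = e.lower_bound, e.lower_inclusive
        assert sum(inside) == 1

    def test_misordered_scheme_rejected(self):
        with pytest.raises(ConfigurationError):
            dm.DoseCoefficientScheme(
                entries=(
                    dm.ReferenceModelEntry("a", 57.0, 0.024, 45.0, True),
                    dm.ReferenceModelEntry("b", 70.0, 0.019, 65.0, False),
                    dm.ReferenceModelEntry("c", 33.0, 0.036, 0.0, False),
                )
            )


class TestPetDose:
    @pytest.mark.parametrize(
        "activity, coefficient, expected",
        [(400.0, 0.019, 7.6), (592.0, 0.019, 11.248), (270.0, 0.019, 5.13), (0.0, 0.019, 0.0)],
    )
    def test_ndrl_worked_examples(self, activity, coefficient, expected):
        assert dm.ed_pet(activity, coefficient) == pytest.approx(expected)

    def test_negative_activity_rejected(self):
        with pytest.raises(InvalidInputError):
            dm.ed_pet(-1.0, 0.019)

    @given(
        st.floats(min_value=0.0, max_value=1e3),
        st.floats(min_value=0.0, max_value=10.0),
    )
    def test_linearity_in_activity(self, activity, k):
        c = 0.019
        assert dm.ed_pet(k * activity, c) == pytest.approx(k * dm.ed_pet(activity, c), abs=1e-9)


class TestWeightScaling:
    @pytest.mark.parametrize(
        "ed, model_w, patient_w, expected",
        [(5.7, 70.0, 70.0, 5.7), (7.6, 70.0, 95.0, 7.6 * 70 / 95), (3.6, 33.0, 44.0, 2.7)],
    )
    def test_examples(self, ed, model_w, patient_w, expected):
        assert dm.ed_pet_weight_scaled(ed, model_w, patient_w) == pytest.approx(expected)

    def test_rounds_to_published_value(self):
        assert round(dm.ed_pet_weight_scaled(7.6, 70.0, 95.0), 1) == 5.6

    @given(st.floats(min_value=40.0, max_value=150.0), st.floats(min_value=1.0, max_value=50.0))
    def test_strictly_decreasing_in_patient_weight(self, w, dw):
        lighter = dm.ed_pet_weight_scaled(5.0, 70.0, w)
        heavier = dm.ed_pet_weight_scaled(5.0, 70.0, w + dw)
        assert heavier < lighter

    def test_nonpositive_patient_weight_rejected(self):
        with pytest.raises(InvalidInputError):
            dm.ed_pet_weight_scaled(5.0, 70.0, 0.0)


class TestBloodVolumeScaling:
    def test_bmi_examples(self):
        assert dm.body_mass_index(70.0, 178.4) == pytest.approx(21.99, abs=0.005)
        assert dm.body_mass_index(88.0, 200.0) == pytest.approx(22.0)

    @pytest.mark.parametrize("height", [None, 0.0, -10.0, math.nan])
    def test_missing_height_gives_absent_bmi(self, height):
        assert dm.body_mass_index(70.0, height) is None

    @pytest.mark.parametrize(
        "bmi, expected", [(22.0, 70.0), (88.0, 35.0), (30.8, 70.0 / math.sqrt(1.4))]
    )
    def test_indexed_blood_volume_examples(self, bmi, expected):
        assert dm.indexed_blood_volume(bmi) == pytest.approx(expected)

    def test_indexed_blood_volume_rejects_nonpositive_bmi(self):
        with pytest.raises(InvalidInputError):
            dm.indexed_blood_volume(0.0)

    @given(st.floats(min_value=5.0, max_value=100.0))
    def test_closure_with_sqrt_bmi(self, bmi):
        """IBV(bmi) · sqrt(bmi/22) returns exactly the 70 ml/kg reference."""
        assert abs(dm.indexed_blood_volume(bmi) * math.sqrt(bmi / 22.0) - 70.0) < 1e-9

    @given(st.floats(min_value=5.0, max_value=99.0), st.floats(min_value=0.01, max_value=10.0))
    def test_scaled_dose_strictly_decreasing_in_bmi(self, bmi, dbmi):
        lo = dm.ed_pet_blood_volume_scaled(5.0, dm.indexed_blood_volume(bmi))
        hi = dm.ed_pet_blood_volume_scaled(5.0, dm.indexed_blood_volume(bmi + dbmi))
        assert hi < lo

    @pytest.mark.parametrize(
        "ed, ibv, expected",
        [(5.0, 70.0, 5.0), (5.0, 35.0, 2.5), (2.85, 59.16, 2.85 * 59.16 / 70.0)],
    )
    def test_scaling_examples(self, ed, ibv, expected):
        assert dm.ed_pet_blood_volume_scaled(ed, ibv) == pytest.approx(expected)


class TestCtAndTotals:
    @pytest.mark.parametrize(
        "dlp, expected", [(0.0, 0.0), (1000.0, 18.0), (427.78, 7.70004)]
    )
    def test_dlp_conversion_examples(self, dlp, expected):
        assert dm.ed_ct_from_dlp(dlp, 0.018) == pytest.approx(expected)

    def test_negative_dlp_rejected(self):
        with pytest.raises(InvalidInputError):
            dm.ed_ct_from_dlp(-1.0)

    @pytest.mark.parametrize(
        "ct, pet, expected", [(7.7, 6.2, 13.9), (7.6, 2.9, 10.5), (0.0, 5.0, 5.0)]
    )
    def test_total_examples(self, ct, pet, expected):
        assert dm.ed_total(ct, pet) == pytest.approx(expected)


class TestDoseResultComposition:
    def test_reference_patient(self):
        rec = dm.PatientRecord("p1", "A", 70.0, 150.0, 420.0, height_cm=178.4)
        res = dm.dose_result_for_patient(rec)
        assert res.model_name == "70 kg adult"
        assert res.ed_pet == pytest.approx(2.85)
        assert res.ed_pet_ws == pytest.approx(2.85)
        assert res.ed_pet_bv == pytest.approx(2.85, abs=0.01)
        assert res.ed_ct == pytest.approx(7.56)
        assert res.ed_total_icrp == pytest.approx(7.56 + 2.85)

    def test_child_coefficient_used_below_45kg(self):
        rec = dm.PatientRecord("p2", "A", 44.0, 150.0, 300.0)
        assert dm.dose_result_for_patient(rec).ed_pet == pytest.approx(5.4)

    def test_missing_height_drops_blood_volume_fields_only(self):
        rec = dm.PatientRecord("p3", "A", 80.0, 200.0, 500.0, height_cm=None)
        res = dm.dose_result_for_patient(rec)
        assert res.ed_pet_bv is None and res.ed_total_bv is None
        assert res.ed_pet > 0 and res.ed_ct > 0 and res.ed_total_ws > 0

    @given(
        weight=st.floats(min_value=35.0, max_value=160.0),
        activity=st.floats(min_value=0.0, max_value=600.0),
        dlp=st.floats(min_value=0.0, max_value=2000.0),
        height=st.one_of(st.none(), st.floats(min_value=120.0, max_value=210.0)),
    )
    def test_totals_equal_their_addends(self, weight, activity, dlp, height):
        rec = dm.PatientRecord("p", "A", weight, activity, dlp, height_cm=height)
        res = dm.dose_result_for_patient(rec)
        assert abs(res.ed_total_icrp - (res.ed_ct + res.ed_pet)) < 1e-12
        assert abs(res.ed_total_ws - (res.ed_ct + res.ed_pet_ws)) < 1e-12
        if height is None:
            assert res.ed_total_bv is None
        else:
            assert abs(res.ed_total_bv - (res.ed_ct + res.ed_pet_bv)) < 1e-12
        for v in (res.ed_pet, res.ed_pet_ws, res.ed_ct, res.ed_total_icrp, res.ed_total_ws):
            assert v >= 0


def test_scheme_yaml_round_trip(tmp_path):
    import yaml

    from petctdose.dosimetry import default_scheme, scheme_from_yaml, scheme_to_dict

    path = tmp_path / "scheme.yaml"
    path.write_text(yaml.safe_dump(scheme_to_dict(default_scheme())))
    assert scheme_from_yaml(path) == default_scheme()


def test_repo_config_matches_default_scheme():
    from pathlib import Path

    cfg = Path(__file__).resolve().parent.parent / "configs" / "dose_coefficients.yaml"
    assert dm.scheme_from_yaml(cfg) == dm.default_scheme()
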