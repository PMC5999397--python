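import math

import pytest
from hypothesis import given, settings, strategies as st

from icescreen import survey
from icescreen.survey import (
    GroupStat,
    SurveySchemaError,
    classify_conditions,
    group_ice_stats,
    group_layer_fractions,
    group_tilt_stats,
    load_survey,
    propagate_measurement_error,
)


@pytest.fixture(scope="module")
def records():
    return load_survey()


@pytest.fixture(scope="module")
def by_id(records):
    return {r.sample_id: r for r in records}


class TestLoadSurvey:
    def test_fixture_has_46_named_samples(self, records):
        assert len(records) == 46
        assert len({r.sample_id for r in records}) == 46
        # one sample appears only in the behaviour table and carries no
        # thickness data or grid type
        r24 = next(r for r in records if r.sample_id == 24)
        assert r24.grid_type is None
        assert all(v is None for v in r24.thickness.values())

    def test_concentration_parsed_from_sample_name(self, by_id):
        assert by_id[22].concentration_mg_ml == pytest.approx(6.0)
        assert by_id[25].concentration_mg_ml == pytest.approx(0.58)

    def test_range_strings_parse_to_tuples(self, by_id):
        assert by_id[4].thickness["center"] == (25.0, 95.0)
        assert by_id[4].thickness["edge"] == (100.0, 210.0)

    def test_malformed_descending_range_rejected(self, tmp_path):
        path = str(survey.default_fixture_path())
        text = open(path).read().replace("25-95", "95-25")
        bad = tmp_path / "bad.csv"
        bad.write_text(text)
        with pytest.raises(SurveySchemaError, match="t_center"):
            load_survey(str(bad))

    def test_round_trip_through_reload_is_stable(self, records, tmp_path):
        import shutil

        copy = tmp_path / "copy.csv"
        shutil.copy(survey.default_fixture_path(), copy)
        again = load_survey(str(copy))
        assert [r.sample_id for r in again] == [r.sample_id for r in records]
        assert [r.thickness for r in again] == [r.thickness for r in records]
        assert [r.tilts for r in again] == [r.tilts for r in records]


class TestErrorPropagation:
    def test_single_measurement_keeps_its_error(self):
        assert propagate_measurement_error([5.0]) == pytest.approx(5.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 200), st.floats(0.01, 50.0))
    def test_equal_errors_reduce_as_one_over_sqrt_n(self, n, err):
        dq = propagate_measurement_error([err] * n)
        assert dq == pytest.approx(err / math.sqrt(n), rel=1e-12)

    def test_eleven_thickness_errors_are_an_order_below_the_sd(self):
        dq = propagate_measurement_error([5.0] * 11)
        assert dq == pytest.approx(1.508, abs=0.001)
        assert dq < 13.0 / 5  # an order of magnitude below a ~13 nm SD

    def test_combined_dispersion_dominates_sd(self):
        g = GroupStat(n=4, mean=10.0, sd=3.0, meas_error_each=5.0,
                      propagated_error=2.5)
        assert g.combined >= g.sd
        assert g.combined == pytest.approx(math.sqrt(3.0**2 + 2.5**2))


class TestIceStats:
    def test_gold_spotiton_center_thirty_nm_over_eleven_samples(self, records):
        g = group_ice_stats(records, "gold_spotiton", "center",
                            exclude_intentionally_thick=True)
        assert g.n == 11
        assert g.mean == pytest.approx(30.0)
        assert round(g.sd) == 13  # population convention
        g1 = group_ice_stats(records, "gold_spotiton", "center",
                             exclude_intentionally_thick=True, ddof=1)
        assert round(g1.sd) == 13  # sample convention rounds identically

    def test_gold_spotiton_edge_sixty_one_nm_over_four_samples(self, records):
        g = group_ice_stats(records, "gold_spotiton", "edge")
        assert g.n == 4
        assert sorted(g.values) == [50.0, 55.0, 65.0, 75.0]
        assert round(g.mean) == 61

    def test_carbon_spotiton_edge_mean(self, records):
        g = group_ice_stats(records, "carbon_spotiton", "edge")
        assert round(g.mean) == 107

    def test_carbon_conventional_edge_mean(self, records):
        g = group_ice_stats(records, "carbon_conventional", "edge")
        assert round(g.mean) == 99

    def test_single_record_group_has_zero_sd_and_five_nm_combined(self, records):
        one = [r for r in records if r.sample_id == 33]  # only gold conventional
        g = group_ice_stats(one, "gold_conventional", "center")
        assert g.n == 1 and g.sd == 0.0
        assert g.combined == pytest.approx(5.0)

    def test_empty_group_rejected(self, records):
        with pytest.raises(ValueError):
            group_ice_stats(records, "gold_conventional", "substrate")


class TestLayerFractions:
    def test_thirty_single_of_thirty_six_gives_eighty_three_percent(self):
        # arithmetic of the counting rule on constructed tokens
        from icescreen.survey import SampleRecord

        def rec(i, tok):
            return SampleRecord(
                sample_id=i, name="x", grid_type="Holey Carbon",
                grid_family="carbon_conventional", concentration_mg_ml=None,
                intentionally_thick=False, affinity_overlay=False,
                no_interface_interaction=False,
                thickness={"center": None, "edge": None, "substrate": None},
                layers={"center": tok, "edge": None, "substrate": None},
                preferred_orientation="no", min_layer_distance=None,
                ice_bottom=None, ice_top=None, region_codes={}, tilts={},
            )

        recs = [rec(i, "1") for i in range(30)] + [rec(30 + i, "2") for i in range(6)]
        f = group_layer_fractions(recs, "center")
        assert f["n_total"] == 36
        assert f["single_percent"] == pytest.approx(83.3, abs=0.1)

    def test_all_double(self):
        f = group_layer_fractions([], "center")
        assert math.isnan(f["single_percent"])

    def test_one_to_two_token_counts_in_both_numerators(self, by_id):
        f = group_layer_fractions([by_id[25]], "center")  # token "1-2"
        assert f["n_single"] == 1 and f["n_double"] == 1 and f["n_total"] == 1


class TestTiltStats:
    def test_center_aggregate_matches_survey_band(self, records):
        g = group_tilt_stats(records, "center")
        assert g.n == 89
        assert 4.0 <= g.mean <= 6.0
        assert g.mean == pytest.approx(4.8, abs=0.15)
        assert g.sd == pytest.approx(3.05, abs=0.1)

    def test_edge_aggregate_matches_survey_band(self, records):
        g = group_tilt_stats(records, "edge")
        assert g.n == 61
        assert g.mean == pytest.approx(6.9, abs=0.1)
        assert g.sd == pytest.approx(3.45, abs=0.1)

    def test_constant_entries(self):
        from icescreen.survey import SampleRecord

        recs = [
            SampleRecord(
                sample_id=i, name="x", grid_type=None, grid_family=None,
                concentration_mg_ml=None, intentionally_thick=False,
                affinity_overlay=False, no_interface_interaction=False,
                thickness={}, layers={}, preferred_orientation="no",
                min_layer_distance=None, ice_bottom=None, ice_top=None,
                region_codes={}, tilts={"center": [(v, v)]},
            )
            for i, v in enumerate([0.0, 10.0])
        ]
        g = group_tilt_stats(recs, "center")
        assert g.mean == pytest.approx(5.0)
        assert g.sd == pytest.approx(5.0)  # population convention


class TestClassification:
    def test_nanodisc_and_streptavidin_samples_are_ideal(self, by_id):
        assert classify_conditions(by_id[25]) == "ideal"
        assert classify_conditions(by_id[46]) == "ideal"

    def test_thick_double_layer_sample_is_neither(self, by_id):
        assert classify_conditions(by_id[7]) == "neither"

    def test_thin_single_layer_without_interaction_evidence_is_near_ideal(self, by_id):
        # sample 21: 15 nm, single layer, no preferred orientation, adsorbed
        assert classify_conditions(by_id[21]) == "near_ideal"

    def test_missing_fields_are_indeterminate_not_guessed(self, by_id):
        assert classify_conditions(by_id[2]) == "indeterminate"  # unknown orientation
        assert classify_conditions(by_id[24]) == "indeterminate"  # no thickness
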