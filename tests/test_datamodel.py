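"""Ingestion, help-minute scoring, presence inference and the zero-coding rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from starhelp import datamodel
from starhelp.datamodel import (
    HelpingLedger,
    ReferentialError,
    SchemaError,
    build_analysis_table,
    infer_presence,
    load_ledger,
    presence_from_individuals,
    score_help_minutes,
)


class TestScoreHelpMinutes:
    @pytest.mark.parametrize(
        "attendance,provisioning,expected",
        [
            (25, 0, 1),     # sub-30-second visits round up to one minute
            (0, 0, 0),
            (61, 60, 3),    # ceil(121 / 60)
            (60, 0, 1),
            (0, 120, 2),
        ],
    )
    def test_examples(self, attendance, provisioning, expected):
        assert score_help_minutes(attendance, provisioning) == expected

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            score_help_minutes(-1, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.floats(0, 1e4), p=st.floats(0, 1e4),
        da=st.floats(0, 1e3), dp=st.floats(0, 1e3),
    )
    def test_monotone_and_positive(self, a, p, da, dp):
        base = score_help_minutes(a, p)
        assert score_help_minutes(a + da, p + dp) >= base
        if a + p > 0:
            assert base >= 1


class TestLoadLedger:
    def test_toy_bundle(self, toy_inputs):
        ledger, nests, individuals = load_ledger(
            toy_inputs["observations.csv"],
            toy_inputs["nests.csv"],
            toy_inputs["individuals.csv"],
            exposure_csv=toy_inputs["exposure.csv"],
        )
        assert len(ledger.visits) == 3
        assert len(nests) == 2
        assert len(individuals) == 5

    def test_empty_observations_ok(self, toy_inputs, tmp_path):
        empty = tmp_path / "empty.csv"
        empty.write_text("helper_id,nest_id,day,help_minutes\n")
        ledger, _, _ = load_ledger(
            empty, toy_inputs["nests.csv"], toy_inputs["individuals.csv"],
            exposure_csv=toy_inputs["exposure.csv"],
        )
        assert len(ledger.visits) == 0

    def test_unknown_nest_named_in_error(self, toy_inputs, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("helper_id,nest_id,day,help_minutes\nH1,N99,5,4\n")
        with pytest.raises(ReferentialError, match="N99"):
            load_ledger(bad, toy_inputs["nests.csv"], toy_inputs["individuals.csv"],
                        exposure_csv=toy_inputs["exposure.csv"])

    def test_missing_column_is_schema_error(self, toy_inputs, tmp_path):
        bad = tmp_path / "nests_bad.csv"
        bad.write_text("nest_id,group,season,mother_id\nN1,G1,1,M1\n")
        with pytest.raises(SchemaError, match="father_id"):
            load_ledger(toy_inputs["observations.csv"], bad,
                        toy_inputs["individuals.csv"],
                        exposure_csv=toy_inputs["exposure.csv"])

    def test_raw_seconds_are_scored(self, toy_inputs, tmp_path):
        raw = tmp_path / "raw.csv"
        raw.write_text(
            "helper_id,nest_id,day,attendance_seconds,provisioning_seconds\n"
            "H1,N1,5,25,0\nH2,N1,5,0,0\n"
        )
        ledger, _, _ = load_ledger(raw, toy_inputs["nests.csv"],
                                   toy_inputs["individuals.csv"],
                                   exposure_csv=toy_inputs["exposure.csv"])
        # zero-help rows never become visits; sub-minute help scores one minute
        assert ledger.visits["help_minutes"].tolist() == [1]


class TestInferPresence:
    def test_span_fills_gaps(self):
        s = pd.DataFrame({"individual": ["A", "A"], "group": ["G", "G"], "season": [1, 3]})
        out = infer_presence(s)
        assert out["season"].tolist() == [1, 2, 3]

    def test_death_gap_truncates_and_drops_isolated_resighting(self):
        s = pd.DataFrame({"individual": ["A", "A"], "group": ["G", "G"], "season": [1, 8]})
        out = infer_presence(s, death_gap=5)
        assert out["season"].tolist() == [1]

    def test_single_sighting(self):
        s = pd.DataFrame({"individual": ["A"], "group": ["G"], "season": [4]})
        assert infer_presence(s)["season"].tolist() == [4]

    def test_empty_sightings(self):
        s = pd.DataFrame(columns=["individual", "group", "season"])
        assert len(infer_presence(s)) == 0


def _toy_table_inputs():
    individuals = pd.DataFrame(
        {
            "id": ["M1", "F1", "H1", "H2", "H3"],
            "sex": ["female", "male", "male", "female", "male"],
            "dispersal": ["immigrant", "resident", "resident", "resident", "immigrant"],
            "group": ["G1"] * 5,
            "first_season": [1] * 5,
            "last_season": [1] * 5,
        }
    )
    nests = pd.DataFrame(
        {"nest_id": ["N1"], "group": ["G1"], "season": [1],
         "mother_id": ["M1"], "father_id": ["F1"]}
    )
    visits = pd.DataFrame(
        {"helper_id": ["H1"], "nest_id": ["N1"], "day": [3], "help_minutes": [10]}
    )
    exposure = pd.DataFrame({"nest_id": ["N1"], "day": [3], "exposure_minutes": [120.0]})
    return individuals, nests, HelpingLedger(visits=visits, exposure=exposure)


class TestBuildAnalysisTable:
    def test_zero_coding_for_present_nonbreeders(self):
        individuals, nests, ledger = _toy_table_inputs()
        presence = presence_from_individuals(individuals)
        table, report = build_analysis_table(ledger, presence, nests, individuals)
        # group of 5: 2 breeders excluded, 3 possible helpers -> rows (10, 0, 0)
        assert len(table) == 3
        assert sorted(table["help_minutes"]) == [0, 0, 10]
        assert report.empty_nest_days == 0

    def test_cross_group_visitor_kept_and_flagged(self):
        individuals, nests, ledger = _toy_table_inputs()
        individuals = pd.concat(
            [individuals, pd.DataFrame([{
                "id": "X9", "sex": "male", "dispersal": "immigrant", "group": "G2",
                "first_season": 1, "last_season": 1}])],
            ignore_index=True,
        )
        ledger.visits = pd.concat(
            [ledger.visits, pd.DataFrame([{
                "helper_id": "X9", "nest_id": "N1", "day": 3, "help_minutes": 4}])],
            ignore_index=True,
        )
        presence = presence_from_individuals(individuals)
        table, report = build_analysis_table(ledger, presence, nests, individuals)
        row = table[table["helper_id"] == "X9"]
        assert len(row) == 1 and row["cross_group"].iloc[0] == 1
        assert report.cross_group_rows == 1
        # the visitor is not zero-filled into other nest-days of G1
        assert (table["helper_id"] == "X9").sum() == 1

    def test_no_present_nonbreeders_warns(self):
        individuals, nests, ledger = _toy_table_inputs()
        individuals = individuals[individuals["id"].isin(["M1", "F1"])]
        ledger.visits = ledger.visits.iloc[:0]
        presence = presence_from_individuals(individuals)
        table, report = build_analysis_table(ledger, presence, nests, individuals)
        assert len(table) == 0
        assert report.empty_nest_days == 1

    def test_help_sum_preserved_on_simulated_data(self, small_dataset, small_table):
        assert small_table["help_minutes"].sum() == small_dataset.ledger.total_help_minutes

    def test_row_count_equals_possible_helpers(self, small_dataset, small_table):
        ds = small_dataset
        presence = presence_from_individuals(ds.individuals)
        nest = ds.nests.set_index("nest_id")
        counts = presence.groupby(["group", "season"]).size().to_dict()
        grp = small_table.groupby(["nest_id", "day"]).size()
        for (nest_id, _day), n_rows in grp.items():
            info = nest.loc[nest_id]
            expected = counts[(info["group"], info["season"])] - 2  # minus the breeders
            assert n_rows == expected

    def test_roundtrip_write_read(self, small_table, tmp_path):
        path = tmp_path / "table.csv"
        datamodel.write_analysis_table(small_table, path)
        back = datamodel.read_analysis_table(path)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), small_table.reset_index(drop=True),
            check_dtype=False,
        )

    def test_offset_is_log_exposure(self, small_table):
        np.testing.assert_allclose(
            datamodel.offset_term(small_table),
            np.log(small_table["exposure_minutes"]),
        )
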