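"""Readers, stratum assignment and observed-count tabulation."""

import datetime as dt

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acsc_equity import AgeBand, ConditionConfig, assign_stratum, tabulate_observed
from acsc_equity.catchment import CatchmentArea
from acsc_equity.core import (
    DuplicateKeyError,
    RowValidationError,
    SchemaError,
    read_encounters,
    read_population,
    read_prevalence,
    write_table,
)

from conftest import encounter_row, encounters_frame

_CFG = ConditionConfig(
    condition="asthma",
    code_prefixes=("J45",),
    window_start=dt.date(2016, 1, 1),
    window_end=dt.date(2017, 1, 1),
    facility_id="HOSP-A",
)


def _catchment(*tracts):
    n = len(tracts)
    return CatchmentArea("HOSP-A", tuple(tracts), 1.0, 0.8, (1,) * n, tuple((i + 1) / n for i in range(n)))


class TestAgeBand:
    @pytest.mark.parametrize(
        "label,lo,hi", [("20-44", 20, 45), ("45-64", 45, 65), ("65+", 65, None), ("0-19", 0, 20)]
    )
    def test_label_round_trip(self, label, lo, hi):
        band = AgeBand.parse(label)
        assert (band.lo, band.hi) == (lo, hi)
        assert band.label == label

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            AgeBand(45, 45)
        with pytest.raises(ValueError):
            AgeBand(-1, 10)


class TestConfig:
    def test_grid_has_expected_cells(self, config):
        assert len(config.stratum_grid()) == 3 * 4 * 2 == 24

    def test_gapped_bands_rejected(self, config):
        with pytest.raises(ValueError, match="contiguous"):
            ConditionConfig(**{**config.to_dict(), "age_bands": ["20-44", "50+"]})

    @pytest.mark.parametrize("field,value", [("catchment_threshold", 0.0), ("catchment_threshold", 1.2), ("code_prefixes", ())])
    def test_invalid_fields_rejected(self, config, field, value):
        with pytest.raises(ValueError):
            ConditionConfig(**{**config.to_dict(), field: value})

    def test_yaml_round_trip(self, tmp_path, config):
        import yaml

        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(config.to_dict()))
        assert ConditionConfig.from_yaml(p) == config


class TestReadEncounters:
    def test_well_formed_rows_pass_through(self, config, write_csv):
        path = write_csv(
            "enc.csv",
            [encounter_row(encounter_id=f"E{i}", patient_id=f"P{i}") for i in range(3)],
        )
        result = read_encounters(path, config)
        assert len(result.data) == 3
        assert result.n_rejected == 0
        assert result.data["date"].iloc[0] == pd.Timestamp("2016-06-15")

    def test_negative_age_names_the_row(self, config, write_csv):
        path = write_csv("enc.csv", [encounter_row(), encounter_row(encounter_id="E2", age=-4)])
        with pytest.raises(RowValidationError, match="row 3"):
            read_encounters(path, config)

    def test_race_label_normalized_via_config_map(self, config, write_csv):
        cfg = config.model_copy(update={"race_map": {"Black": "AA"}})
        path = write_csv("enc.csv", [encounter_row(race_ethnicity="Black")])
        result = read_encounters(path, cfg)
        assert result.data["race_ethnicity"].iloc[0] == "AA"

    def test_unknown_race_label_rejected(self, config, write_csv):
        path = write_csv("enc.csv", [encounter_row(race_ethnicity="Martian")])
        with pytest.raises(RowValidationError, match="race"):
            read_encounters(path, config)

    def test_collect_mode_reports_reasons(self, config, write_csv):
        path = write_csv(
            "enc.csv",
            [
                encounter_row(),
                encounter_row(encounter_id="E2", date="not-a-date"),
                encounter_row(encounter_id="E1", patient_id="P9"),  # duplicate id
            ],
        )
        result = read_encounters(path, config, strict=False)
        assert len(result.data) == 1
        reasons = set(result.rejected["reason"])
        assert any("date" in r for r in reasons)
        assert any("duplicate" in r for r in reasons)

    def test_missing_column_is_schema_error(self, config, tmp_path):
        p = tmp_path / "enc.csv"
        p.write_text("patient_id,encounter_id\nP1,E1\n")
        with pytest.raises(SchemaError, match="missing required column"):
            read_encounters(p, config)

    def test_round_trip_is_identity(self, config, write_csv, tmp_path):
        path = write_csv("enc.csv", [encounter_row(encounter_id=f"E{i}", age=20 + i) for i in range(4)])
        first = read_encounters(path, config).data
        out = tmp_path / "again.csv"
        write_table(first, out)
        second = read_encounters(out, config).data
        pd.testing.assert_frame_equal(first.drop(columns="row"), second.drop(columns="row"))


class TestReadPopulationAndPrevalence:
    def _pop_row(self, tract="T001", band="20-44", race="AA", gender="F", population=100):
        return dict(tract_id=tract, age_band=band, race=race, gender=gender, population=population)

    def test_zero_population_accepted(self, config, write_csv):
        path = write_csv("pop.csv", [self._pop_row(population=0)])
        assert read_population(path, config).data["population"].iloc[0] == 0

    def test_negative_population_rejected(self, config, write_csv):
        path = write_csv("pop.csv", [self._pop_row(population=-5)])
        with pytest.raises(RowValidationError):
            read_population(path, config)

    def test_duplicate_tract_stratum_is_error(self, config, write_csv):
        path = write_csv("pop.csv", [self._pop_row(), self._pop_row(population=7)])
        with pytest.raises(DuplicateKeyError):
            read_population(path, config)

    def test_prevalence_above_one_rejected(self, config, write_csv):
        path = write_csv(
            "prev.csv",
            [
                dict(condition="asthma", age_band="", race="", gender="", prevalence=0.1),
                dict(condition="asthma", age_band="", race="AA", gender="", prevalence=1.2),
            ],
        )
        with pytest.raises(RowValidationError, match=r"\[0, 1\]"):
            read_prevalence(path, config)

    def test_overall_prevalence_required(self, config, write_csv):
        path = write_csv(
            "prev.csv",
            [dict(condition="asthma", age_band="", race="AA", gender="", prevalence=0.1)],
        )
        with pytest.raises(RowValidationError, match="overall"):
            read_prevalence(path, config)


class TestAssignStratum:
    def test_young_adult_example(self, config):
        s = assign_stratum(27, "F", "AA", config)
        assert (s.age_band.label, s.race, s.gender) == ("20-44", "AA", "F")

    def test_half_open_boundary(self, config):
        assert assign_stratum(44, "F", "AA", config).age_band.label == "20-44"
        assert assign_stratum(45, "F", "AA", config).age_band.label == "45-64"

    def test_out_of_range_age_flagged_not_binned(self, config):
        assert assign_stratum(19, "F", "AA", config) is None

    def test_unconfigured_labels_are_errors(self, config):
        with pytest.raises(ValueError):
            assign_stratum(30, "F", "Martian", config)
        with pytest.raises(ValueError):
            assign_stratum(-1, "F", "AA", config)

    @settings(derandomize=True, max_examples=200)
    @given(age=st.integers(min_value=20, max_value=120), race=st.integers(0, 3), gender=st.booleans())
    def test_grid_exhaustive_and_exclusive(self, age, race, gender):
        """Every in-range record maps to exactly one of the 24 cells."""
        cfg = _CFG
        s = assign_stratum(age, cfg.genders[gender], cfg.races[race], cfg)
        containing = [b for b in cfg.age_bands if b.contains(age)]
        assert containing == [s.age_band]
        assert s in cfg.stratum_grid()


class TestTabulateObserved:
    def test_totals_match_printed_drilldown_style_counts(self, config):
        rows = []
        k = 0
        for pid in range(5):
            for _ in range(2):  # two encounters per patient
                rows.append(encounter_row(patient_id=f"P{pid}", encounter_id=f"E{k}", age=30))
                k += 1
        table = tabulate_observed(encounters_frame(rows), _catchment("T001"), config)
        cell = table.loc[("20-44", "AA", "F")]
        assert (cell["observed"], cell["patients"]) == (10, 5)
        assert table["observed"].sum() == table.attrs["n_filtered"]

    def test_four_filters_applied(self, config):
        rows = [
            encounter_row(encounter_id="E1"),
            encounter_row(encounter_id="E2", diagnosis_code="E11.9"),  # wrong condition
            encounter_row(encounter_id="E3", facility_id="HOSP-B"),
            encounter_row(encounter_id="E4", date="2017-06-01"),  # outside window
            encounter_row(encounter_id="E5", tract_id="T999"),  # outside catchment
        ]
        table = tabulate_observed(encounters_frame(rows), _catchment("T001"), config)
        assert table["observed"].sum() == 1

    def test_empty_table_gives_zero_grid_with_warning(self, config):
        rows = [encounter_row(facility_id="OTHER")]
        table = tabulate_observed(encounters_frame(rows), _catchment("T001"), config)
        assert table["observed"].sum() == 0
        assert len(table) == 24
        assert table.attrs["empty"]

    def test_out_of_range_ages_counted_separately(self, config):
        rows = [encounter_row(), encounter_row(encounter_id="E2", age=12)]
        table = tabulate_observed(encounters_frame(rows), _catchment("T001"), config)
        assert table["observed"].sum() == 1
        assert table.attrs["n_out_of_range"] == 1

    def test_patient_crossing_band_boundary_counts_in_both_strata(self, config):
        rows = [
            encounter_row(encounter_id="E1", age=44, date="2016-01-05"),
            encounter_row(encounter_id="E2", age=45, date="2016-11-05"),
        ]
        table = tabulate_observed(encounters_frame(rows), _catchment("T001"), config)
        assert table.loc[("20-44", "AA", "F"), "patients"] == 1
        assert table.loc[("45-64", "AA", "F"), "patients"] == 1
        assert table["patients"].sum() == 2
        assert table.attrs["distinct_patients"] == 1
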