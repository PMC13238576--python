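import numpy as np
import pandas as pd
import pytest

from ntheat import outcomes
from ntheat.outcomes import (
    aggregate_counts,
    assign_exposure_region,
    derive_demographics,
    load_condition_groups,
    parse_ed_records,
)


@pytest.fixture(scope="module")
def groups():
    return load_condition_groups()


class TestConditionGroups:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("K52", "digestive"),
            ("K52.9", "digestive"),          # decimal child of a 3-char range
            ("T67", "effects_heat_light"),    # excluded from the injury ranges
            ("T66", "injury"),
            ("T68", "injury"),
            ("Z99", outcomes.UNCLASSIFIED),
            ("U07.1", "infectious"),          # decimal-specific range endpoint
            ("U07.3", outcomes.UNCLASSIFIED),
            ("R19.0", "digestive"),           # decimal-specific single
            ("R19.1", outcomes.UNCLASSIFIED),
            ("R06.1", "respiratory"),         # inside decimal range R06.0-R06.2
            ("R06.3", outcomes.UNCLASSIFIED),
            ("A00", "infectious"),
            ("E14", "diabetes"),
            ("R05", "respiratory"),
        ],
    )
    def test_range_semantics(self, groups, code, expected):
        assert groups.map_code(code) == expected

    def test_malformed_code_unclassified(self, groups):
        assert groups.map_code("banana") == outcomes.UNCLASSIFIED
        assert groups.map_code(None) == outcomes.UNCLASSIFIED

    def test_eleven_groups_in_order(self, groups):
        assert len(groups.names) == 11
        assert groups.names[0] == "infectious"
        assert groups.names[-1] == "effects_heat_light"

    def test_partition_every_code_maps_once(self, groups):
        rng = np.random.default_rng(0)
        letters = list("ABEFIJKLMNRSTUZ")
        codes = [
            f"{rng.choice(letters)}{rng.integers(0, 100):02d}" for _ in range(300)
        ]
        mapped = [groups.map_code(c) for c in codes]
        assert len(mapped) == 300  # total function: every code maps somewhere
        assert set(mapped) <= set(groups.names) | {outcomes.UNCLASSIFIED}


def _lines(rows):
    df = pd.DataFrame(rows, columns=outcomes.ED_COLUMNS)
    return df.astype(str)


class TestParseEDRecords:
    def test_well_formed_row(self):
        df, report = parse_ed_records(
            _lines([["2002-01-05", "H:A", "A", "nt", "30", "F", "Aboriginal", "K52"]])
        )
        assert len(df) == 1 and report["n_kept"] == 1
        assert df.loc[0, "sex"] == "female"
        assert df.loc[0, "indigenous_status"] == "aboriginal"

    def test_unknown_sex_kept(self):
        df, _ = parse_ed_records(
            _lines([["2002-01-05", "H:A", "A", "nt", "30", "U", "?", "K52"]])
        )
        assert df.loc[0, "sex"] == "unknown"
        assert df.loc[0, "indigenous_status"] == "unknown"

    def test_bad_date_rejected_with_reason(self):
        df, report = parse_ed_records(
            _lines(
                [
                    ["2024-13-40", "H:A", "A", "nt", "30", "m", "a", "K52"],
                    ["2002-01-05", "H:A", "A", "nt", "30", "m", "a", "K52"],
                ]
            )
        )
        assert len(df) == 1
        assert report["rejected"]["bad_date"] == 1

    def test_missing_column_rejects_file(self):
        with pytest.raises(ValueError, match="mandatory"):
            parse_ed_records(pd.DataFrame({"date": ["2002-01-05"]}))

    def test_negative_age_becomes_missing(self):
        df, _ = parse_ed_records(
            _lines([["2002-01-05", "H:A", "A", "nt", "-3", "m", "a", "K52"]])
        )
        assert np.isnan(df.loc[0, "age_years"])


HOSPITALS = {"H:A": "A", "H:B": "B"}
REGIONS = {"A", "B"}


class TestExposureRegion:
    def _records(self, rows):
        df, _ = parse_ed_records(_lines(rows))
        return df

    def test_resident_keeps_own_region(self):
        df = self._records([["2002-01-05", "H:B", "A", "nt", "30", "m", "a", "K52"]])
        out, _ = assign_exposure_region(df, HOSPITALS, REGIONS)
        assert out.loc[0, "exposure_region"] == "A"
        assert out.loc[0, "residency"] == "resident"

    def test_visitor_maps_to_hospital_region(self):
        df = self._records([["2002-01-05", "H:B", "NSW1", "non_nt", "30", "m", "a", "K52"]])
        out, _ = assign_exposure_region(df, HOSPITALS, REGIONS)
        assert out.loc[0, "exposure_region"] == "B"
        assert out.loc[0, "residency"] == "visitor"

    def test_blank_address_maps_to_hospital_region(self):
        df = self._records([["2002-01-05", "H:B", "", "", "30", "m", "a", "K52"]])
        out, _ = assign_exposure_region(df, HOSPITALS, REGIONS)
        assert out.loc[0, "exposure_region"] == "B"
        assert out.loc[0, "residency"] == "unknown"

    def test_unknown_hospital_rejected(self):
        df = self._records([["2002-01-05", "H:Z", "A", "nt", "30", "m", "a", "K52"]])
        out, report = assign_exposure_region(df, HOSPITALS, REGIONS)
        assert len(out) == 0
        assert report["rejected_unknown_hospital"] == 1

    def test_idempotent_and_in_registry(self):
        df = self._records(
            [
                ["2002-01-05", "H:B", "A", "nt", "30", "m", "a", "K52"],
                ["2002-01-05", "H:A", "X9", "non_nt", "30", "m", "a", "K52"],
                ["2002-01-05", "H:A", "", "", "30", "m", "a", "K52"],
            ]
        )
        once, _ = assign_exposure_region(df, HOSPITALS, REGIONS)
        twice, _ = assign_exposure_region(once, HOSPITALS, REGIONS)
        assert (once["exposure_region"] == twice["exposure_region"]).all()
        assert set(once["exposure_region"]) <= REGIONS


class TestDemographics:
    def test_age_band_edges(self):
        df, _ = parse_ed_records(
            _lines(
                [
                    ["2002-01-05", "H:A", "A", "nt", str(a), "m", "a", "K52"]
                    for a in (0, 4, 5, 18, 19, 49, 50, 64, 65, 90)
                ]
            )
        )
        out = derive_demographics(df)
        assert list(out["age_band"]) == [
            "<5", "<5", "5-18", "5-18", "19-49", "19-49", "50-64", "50-64", "65+", "65+",
        ]

    def test_missing_age_unknown(self):
        df, _ = parse_ed_records(
            _lines([["2002-01-05", "H:A", "A", "nt", "", "m", "a", "K52"]])
        )
        assert derive_demographics(df).loc[0, "age_band"] == "unknown"

    @pytest.mark.parametrize(
        "scheme,decile,expected",
        [
            ("methods", 3, "most_disadvantaged"),
            ("methods", 7, "moderate"),
            ("methods", 8, "most_advantaged"),
            ("table", 7, "most_advantaged"),
            ("table", 6, "moderate"),
        ],
    )
    def test_irsd_schemes(self, scheme, decile, expected):
        df, _ = parse_ed_records(
            _lines([["2002-01-05", "H:A", "A", "nt", "30", "m", "a", "K52"]])
        )
        out = derive_demographics(df, {"A": decile}, irsd_scheme=scheme)
        assert out.loc[0, "irsd_band"] == expected

    def test_partition_age_and_condition(self, tiny_frames):
        df, _ = parse_ed_records(tiny_frames["ed"])
        out = derive_demographics(df)
        assert out["age_band"].notna().all()
        assert out["condition_group"].notna().all()
        assert out["age_band"].value_counts().sum() == len(out)
        assert out["condition_group"].value_counts().sum() == len(out)


def _mini_calendar():
    dates = pd.date_range("2002-01-01", periods=10)
    rows = []
    for r in ("A", "B"):
        for i, d in enumerate(dates):
            rows.append(
                {
                    "region_id": r,
                    "date": d,
                    "exposure_level": "low" if (r == "A" and i >= 7) else "none",
                }
            )
    return pd.DataFrame(rows)


class TestAggregateCounts:
    def _records(self, rows):
        df, _ = parse_ed_records(_lines(rows))
        df, _ = assign_exposure_region(df, HOSPITALS, REGIONS)
        return df

    def test_counts_conserved_and_zero_filled(self):
        recs = self._records(
            [["2002-01-03", "H:A", "A", "nt", "30", "m", "a", "K52"]] * 3
            + [["2002-01-04", "H:B", "B", "nt", "30", "m", "a", "K52"]]
        )
        out, report = aggregate_counts(recs, _mini_calendar())
        assert len(out) == 20  # zero-filled region-day grid
        assert out["count"].sum() == 4
        day = out[(out["region_id"] == "A") & (out["date"] == "2002-01-03")]
        assert day["count"].iloc[0] == 3

    def test_filter_conservation(self):
        recs = self._records(
            [
                ["2002-01-03", "H:A", "A", "nt", "30", "m", "Aboriginal", "K52"],
                ["2002-01-03", "H:A", "A", "nt", "30", "m", "non-aboriginal", "K52"],
                ["2002-01-04", "H:A", "A", "nt", "30", "m", "Aboriginal", "K52"],
            ]
        )
        out, _ = aggregate_counts(
            recs, _mini_calendar(), record_filter=recs["indigenous_status"] == "aboriginal"
        )
        assert out["count"].sum() == 2

    def test_out_of_span_excluded_and_counted(self):
        recs = self._records(
            [
                ["2001-12-31", "H:A", "A", "nt", "30", "m", "a", "K52"],
                ["2002-01-05", "H:A", "A", "nt", "30", "m", "a", "K52"],
            ]
        )
        out, report = aggregate_counts(recs, _mini_calendar())
        assert report["n_records_outside_span"] == 1
        assert out["count"].sum() == 1

    def test_covariates_joined(self):
        recs = self._records([["2002-01-08", "H:A", "A", "nt", "30", "m", "a", "K52"]])
        holidays = pd.DataFrame({"date": ["2002-01-08"], "scope": ["all"]})
        pm25 = pd.DataFrame(
            {"region_id": ["A"], "date": ["2002-01-08"], "pm25_ugm3": [7.5]}
        )
        out, report = aggregate_counts(recs, _mini_calendar(), holidays, pm25)
        row = out[(out["region_id"] == "A") & (out["date"] == "2002-01-08")].iloc[0]
        assert row["holiday"] and row["exposure_level"] == "low"
        assert row["pm25_ugm3"] == pytest.approx(7.5)
        assert report["n_missing_pm25"] == 19  # only one region-day supplied

    def test_stratum_keys_iso_dow(self):
        out, _ = aggregate_counts(self._records([]), _mini_calendar())
        jan7 = out[out["date"] == "2002-01-07"].iloc[0]
        assert jan7["dow"] == 1  # 2002-01-07 was a Monday
        assert (out["month"] == 1).all() and (out["year"] == 2002).all()
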