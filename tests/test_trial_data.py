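"""Trial-record validation, derived strata and stratified summaries."""

import datetime as dt
import itertools

import numpy as np
import pytest

from incidentalg.synthetic import generate_trials
from incidentalg.trial_data import (
    SeasonCalendar,
    TrialValidationError,
    assign_density_quartile,
    assign_season,
    default_calendars,
    filter_available,
    read_trials,
    summaries_to_frame,
    summarize_activity,
    summarize_detection,
    write_trials,
)

from conftest import make_record


class TestReadTrials:
    def test_round_trip(self, tmp_path):
        records = [
            make_record(turbine_id=f"T{i}", found=(i % 2 == 0))
            for i in range(3)
        ]
        records = [
            r if r.found else make_record(turbine_id=r.turbine_id,
                                          found=False, detection_date=None,
                                          activity=None)
            for r in records
        ]
        path = tmp_path / "trials.csv"
        write_trials(records, path)
        back = read_trials(path)
        assert back == records

    def test_found_but_unavailable_names_row(self, tmp_path):
        records = [make_record(), make_record()]
        path = tmp_path / "trials.csv"
        write_trials(records, path)
        text = path.read_text().splitlines()
        text[2] = text[2].replace("true,true", "false,true")
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(TrialValidationError, match="row 2"):
            read_trials(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "trials.csv"
        path.write_text("site_id,turbine_id\nA,T1\n")
        with pytest.raises(TrialValidationError, match="missing column"):
            read_trials(path)

    def test_unparseable_date_names_row(self, tmp_path):
        path = tmp_path / "trials.csv"
        write_trials([make_record()], path)
        path.write_text(path.read_text().replace("2021-07-10", "not-a-date"))
        with pytest.raises(TrialValidationError, match="row 1"):
            read_trials(path)

    def test_distance_beyond_search_radius_rejected(self):
        with pytest.raises(TrialValidationError, match="distance"):
            make_record(distance_m=101.0).validate()

    def test_found_without_detection_date_rejected(self):
        with pytest.raises(TrialValidationError, match="detection_date"):
            make_record(detection_date=None).validate()

    def test_synthetic_scenario_round_trip(self, tmp_path, study_records):
        path = tmp_path / "synthetic.csv"
        write_trials(study_records, path)
        assert len(read_trials(path)) == len(study_records)


class TestSeasonAssignment:
    def test_published_calendar_examples(self, calendars):
        frontier = calendars["Frontier I"]
        assert frontier.season_of(dt.date(2021, 7, 1)) == "summer"
        # winter wraps the calendar-year boundary
        assert frontier.season_of(dt.date(2022, 1, 10)) == "winter"

    def test_boundary_date_belongs_to_starting_season(self, calendars):
        frontier = calendars["Frontier I"]
        assert frontier.season_of(dt.date(2021, 3, 16)) == "spring"
        assert frontier.season_of(dt.date(2021, 3, 15)) == "winter"

    def test_all_default_calendars_tile_the_year(self, calendars):
        day = dt.date(2021, 1, 1)
        for cal in calendars.values():
            seen = set()
            while day.year == 2021:
                seen.add(cal.season_of(day))
                day += dt.timedelta(days=1)
            day = dt.date(2021, 1, 1)
            assert seen == {"spring", "summer", "fall", "winter"}

    def test_leap_day_assigned(self, calendars):
        # Feb 29 falls inside every site's winter despite 02-28 range ends
        for cal in calendars.values():
            assert cal.season_of(dt.date(2024, 2, 29)) == "winter"

    def test_gap_calendar_rejected(self):
        with pytest.raises(ValueError, match="uncovered"):
            SeasonCalendar.from_strings("X", {
                "spring": ["03-01", "05-31"], "summer": ["06-01", "08-31"],
                "fall": ["09-01", "11-30"], "winter": ["12-05", "02-28"],
            })

    def test_record_site_must_match_calendar(self, calendars):
        rec = make_record(site_id="Frontier I")
        with pytest.raises(ValueError, match="Wild Horse"):
            assign_season(rec, calendars["Wild Horse"])


class TestDensityQuartile:
    @pytest.mark.parametrize("distance, expected", [
        (0.0, "near"), (33.0, "near"), (33.001, "near_mid"),
        (45.0, "near_mid"), (45.5, "far_mid"), (61.0, "far_mid"),
        (61.5, "far"), (100.0, "far"),
    ])
    def test_boundaries(self, distance, expected):
        assert assign_density_quartile(distance) == expected

    @pytest.mark.parametrize("bad", [-0.1, 100.1])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            assign_density_quartile(bad)

    def test_bin_monotone_in_distance(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        order = {q: i for i, q in enumerate(
            ("near", "near_mid", "far_mid", "far"))}

        @given(d1=st.floats(0, 100), d2=st.floats(0, 100))
        @settings(max_examples=100, derandomize=True)
        def check(d1, d2):
            lo, hi = sorted((d1, d2))
            assert (order[assign_density_quartile(lo)]
                    <= order[assign_density_quartile(hi)])

        check()


class TestFilterAvailable:
    def test_counts(self):
        records = [make_record(found=False, detection_date=None,
                               available=(i % 5 != 0)) for i in range(20)]
        kept, excluded = filter_available(records)
        assert excluded == 4
        assert len(kept) == 16

    def test_all_available_identity(self):
        records = [make_record() for _ in range(3)]
        kept, excluded = filter_available(records)
        assert kept == records and excluded == 0

    def test_empty(self):
        assert filter_available([]) == ([], 0)


class TestSummarizeDetection:
    def test_global_summary_matches_counts(self):
        records = (
            [make_record() for _ in range(444)]
            + [make_record(found=False, detection_date=None, activity=None)
               for _ in range(474)]
        )
        [summary] = summarize_detection(records)
        assert summary.n_available == 918
        assert summary.n_found == 444
        assert summary.p_hat == pytest.approx(444 / 918)
        assert round(summary.p_hat, 2) == 0.48

    def test_saturated_stratum(self):
        records = [make_record(viewshed_class="low") for _ in range(5)]
        [summary] = summarize_detection(records, ["viewshed_class"])
        assert summary.p_hat == 1.0

    def test_rejects_unavailable_records(self):
        rec = make_record(available=False, found=False, detection_date=None)
        with pytest.raises(ValueError, match="filter_available"):
            summarize_detection([rec])

    def test_stratified_counts_conserve_global(self, study_records, calendars):
        available, _ = filter_available(study_records)
        [global_summary] = summarize_detection(available)
        for strat in (["site"], ["season"], ["site", "viewshed_class"],
                      ["density_quartile", "season"]):
            parts = summarize_detection(available, strat, calendars)
            assert sum(s.n_available for s in parts) == global_summary.n_available
            assert sum(s.n_found for s in parts) == global_summary.n_found

    def test_permutation_invariance(self, study_records, rng):
        available, _ = filter_available(study_records)
        before = summarize_detection(available, ["site"])
        shuffled = list(available)
        rng.shuffle(shuffled)
        assert summarize_detection(shuffled, ["site"]) == before

    def test_recovers_constant_rate_at_large_n(self, single_site_config):
        # all logit coefficients zero: every cell has true p = 0.5
        config = single_site_config
        config = type(config)(**{**config.__dict__,
                                 "months": 800, "seed": 17,
                                 "_fall_model": config.fall_model})
        records = generate_trials(config)
        available, _ = filter_available(records)
        [summary] = summarize_detection(available)
        n = summary.n_available
        se = np.sqrt(0.25 / n)
        assert n > 10_000
        assert abs(summary.p_hat - 0.5) < 3 * se


class TestSummarizeActivity:
    def test_published_style_proportions(self):
        counts = {"routine_inspection": 106, "driving": 96,
                  "maintenance": 91, "other": 14}
        records = [
            make_record(activity=act)
            for act, n in counts.items()
            for _ in range(n)
        ]
        df = summarize_activity(records)
        by_act = df.set_index("activity")
        assert by_act.loc["routine_inspection", "n"] == 106
        rounded = {a: round(p * 100) for a, p in
                   zip(df["activity"], df["proportion"])}
        assert rounded == {"routine_inspection": 35, "driving": 31,
                           "maintenance": 30, "other": 5}

    def test_no_activity_recorded(self):
        records = [make_record(activity=None) for _ in range(5)]
        assert summarize_activity(records).empty

    def test_multinomial_recovery(self, single_site_config):
        records = generate_trials(single_site_config)
        df = summarize_activity(records)
        weights = single_site_config.activity_weights
        total = sum(weights.values())
        for row in df.itertuples():
            expected = weights[row.activity] / total
            se = np.sqrt(expected * (1 - expected) / df["n"].sum())
            assert abs(row.proportion - expected) < 4 * se


def test_summaries_to_frame_shape(study_records, calendars):
    available, _ = filter_available(study_records)
    df = summaries_to_frame(
        summarize_detection(available, ["site", "season"], calendars))
    assert set(df.columns) == {"site", "season", "n_available", "n_found",
                               "p_hat"}
    assert (df["n_found"] <= df["n_available"]).all()
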