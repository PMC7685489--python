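"""Visit collapsing, effort arithmetic and weekly aggregation."""

import datetime
import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from watervisits.visits import (EffortInconsistencyError, SchemaError,
                                WeekScheme, collapse_visits, compute_effort,
                                read_detections, week_scheme_from_log,
                                weekly_counts)

GAP = datetime.timedelta(hours=1)


def make_detections(times, loc="L1", species="bighorn", counts=None):
    return pd.DataFrame({
        "site": "S1", "location": loc,
        "timestamp": pd.to_datetime(times), "species": species,
        "n_in_image": counts if counts is not None else [1] * len(times),
    })


def brute_force_partition(times, gap):
    """O(n^2) reference partitioner: two images share a visit iff every
    consecutive step between them is strictly below the gap."""
    times = sorted(times)
    visits = []
    i = 0
    while i < len(times):
        j = i
        while j + 1 < len(times) and (times[j + 1] - times[j]) < gap:
            j += 1
        visits.append(times[i:j + 1])
        i = j + 1
    return visits


class TestCollapseVisits:
    def test_sixty_minute_gap_starts_new_visit(self):
        det = make_detections(["2020-01-01 10:00", "2020-01-01 10:30",
                               "2020-01-01 11:30"])
        vis = collapse_visits(det, gap=GAP)
        assert len(vis) == 2
        assert list(vis["n_images"]) == [2, 1]
        assert vis["start"].iloc[1] == pd.Timestamp("2020-01-01 11:30")

    def test_single_image_visit(self):
        det = make_detections(["2020-01-01 10:00"], counts=[4])
        vis = collapse_visits(det, gap=GAP)
        assert len(vis) == 1
        assert vis["group_size"].iloc[0] == 4
        assert vis["start"].iloc[0] == vis["end"].iloc[0]

    def test_group_size_is_max_over_images(self):
        det = make_detections(["2020-01-01 10:00", "2020-01-01 10:10",
                               "2020-01-01 10:20"], counts=[2, 7, 3])
        vis = collapse_visits(det, gap=GAP)
        assert len(vis) == 1
        assert vis["group_size"].iloc[0] == 7

    def test_empty_input(self):
        assert len(collapse_visits(make_detections([]))) == 0

    def test_species_partitioned_independently(self):
        a = make_detections(["2020-01-01 10:00"], species="bighorn")
        b = make_detections(["2020-01-01 10:30"], species="coyote")
        vis = collapse_visits(pd.concat([a, b]), gap=GAP)
        assert len(vis) == 2

    def test_matches_bruteforce_on_random_streams(self):
        rng = np.random.default_rng(7)
        base = pd.Timestamp("2020-06-01")
        for _ in range(200):
            n = int(rng.integers(1, 40))
            # minute offsets with many near-60 gaps, incl. exactly 60
            gaps = rng.choice([5, 30, 59, 60, 61, 120], size=n)
            offs = np.cumsum(gaps)
            times = [base + pd.Timedelta(minutes=int(o)) for o in offs]
            det = make_detections(times)
            vis = collapse_visits(det, gap=GAP)
            oracle = brute_force_partition(times, GAP)
            assert len(vis) == len(oracle)
            assert list(vis["n_images"]) == [len(v) for v in oracle]
            assert list(vis["start"]) == [v[0] for v in oracle]
            assert list(vis["end"]) == [v[-1] for v in oracle]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=200), min_size=1,
                    max_size=60))
    def test_gap_property_holds_for_any_stream(self, minute_gaps):
        """Within a visit all image gaps are < 1 h; between visits >= 1 h."""
        base = pd.Timestamp("2020-01-01")
        times = [base + pd.Timedelta(minutes=int(o))
                 for o in np.cumsum(minute_gaps)]
        det = make_detections(times)
        vis = collapse_visits(det, gap=GAP)
        bounds = list(zip(vis["start"], vis["end"]))
        starts = vis["start"].tolist()
        ends = vis["end"].tolist()
        for prev_end, nxt_start in zip(ends[:-1], starts[1:]):
            assert nxt_start - prev_end >= GAP
        for s, e in bounds:
            inside = [t for t in times if s <= t <= e]
            for a, b in zip(inside[:-1], inside[1:]):
                assert b - a < GAP
        assert vis["n_images"].sum() == len(times)

    def test_partition_property(self, small_dataset):
        """Every image lands in exactly one visit; image counts conserved."""
        det = small_dataset.detections
        vis = collapse_visits(det, gap=GAP)
        n_in = det.groupby(["location", "species"]).size()
        n_out = vis.groupby(["location", "species"])["n_images"].sum()
        pd.testing.assert_series_equal(n_in, n_out, check_names=False)
        # consecutive visits separated by >= gap
        for (_, _), grp in vis.groupby(["location", "species"]):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            assert (starts[1:] - ends[:-1] >= np.timedelta64(1, "h")).all()


class TestReadDetections:
    def test_well_formed_roundtrip(self, small_dataset, tmp_path):
        p = tmp_path / "det.csv"
        small_dataset.detections.to_csv(p, index=False)
        df = read_detections(p)
        assert len(df) == len(small_dataset.detections)
        got = df.sort_values(["location", "species", "timestamp"])
        exp = small_dataset.detections.sort_values(
            ["location", "species", "timestamp"])
        assert (got["n_in_image"].to_numpy()
                == exp["n_in_image"].to_numpy()).all()
        assert (got["timestamp"].to_numpy()
                == exp["timestamp"].to_numpy()).all()

    def test_bad_rows_rejected_and_logged(self, caplog):
        rows = ["site,location,timestamp,species,n_in_image"]
        rows += [f"S1,L1,2020-01-01 10:{i:02d},bighorn,1" for i in range(9)]
        rows.insert(5, "S1,L1,not-a-time,bighorn,1")
        with caplog.at_level("WARNING"):
            df = read_detections(io.StringIO("\n".join(rows)))
        assert len(df) == 9
        assert "1 malformed" in caplog.text
        assert "5" in caplog.text  # the offending data line number

    def test_missing_column_is_schema_error(self):
        csv = io.StringIO("site,location,species\nS1,L1,bighorn\n")
        with pytest.raises(SchemaError, match="timestamp"):
            read_detections(csv)

    def test_column_remapping(self):
        csv = io.StringIO(
            "Station,Catchment,DateTime,Animal,Count\n"
            "S1,L1,2020-01-01 10:00,bighorn,2\n")
        df = read_detections(csv, schema={
            "site": "Station", "location": "Catchment",
            "timestamp": "DateTime", "species": "Animal",
            "n_in_image": "Count"})
        assert df["n_in_image"].iloc[0] == 2


class TestComputeEffort:
    WEEKS = WeekScheme(anchor=datetime.date(2020, 1, 6))

    def test_full_week(self):
        log = pd.DataFrame({"location": ["L1"],
                            "start": ["2020-01-06"], "end": ["2020-01-13"]})
        eff = compute_effort(log, self.WEEKS)
        assert eff.loc[eff["week"] == 0, "camera_days"].iloc[0] == 7.0

    def test_partial_week(self):
        log = pd.DataFrame({"location": ["L1"], "start": ["2020-01-06"],
                            "end": ["2020-01-09 12:00"]})
        eff = compute_effort(log, self.WEEKS)
        assert eff["camera_days"].iloc[0] == pytest.approx(3.5)

    def test_overlapping_intervals_merged(self, caplog):
        log = pd.DataFrame({"location": ["L1", "L1"],
                            "start": ["2020-01-06", "2020-01-08"],
                            "end": ["2020-01-10", "2020-01-13"]})
        with caplog.at_level("WARNING"):
            eff = compute_effort(log, self.WEEKS)
        assert eff["camera_days"].iloc[0] == pytest.approx(7.0)
        assert "overlapping" in caplog.text

    def test_matches_minute_grid_oracle(self):
        rng = np.random.default_rng(11)
        base = pd.Timestamp("2020-01-06")
        for _ in range(25):
            n_iv = int(rng.integers(1, 5))
            starts = rng.integers(0, 21 * 1440, size=n_iv)
            lengths = rng.integers(60, 7 * 1440, size=n_iv)
            log = pd.DataFrame({
                "location": "L1",
                "start": [base + pd.Timedelta(minutes=int(s))
                          for s in starts],
                "end": [base + pd.Timedelta(minutes=int(s + l))
                        for s, l in zip(starts, lengths)],
            })
            eff = compute_effort(log, self.WEEKS)
            # minute-grid occupancy of the interval union
            span_min = int(starts.max() + lengths.max()) + 1440 * 7
            grid = np.zeros(span_min, dtype=bool)
            for s, l in zip(starts, lengths):
                grid[s:s + l] = True
            for _, row in eff.iterrows():
                w0 = int(row["week"]) * 7 * 1440
                expect = grid[w0:w0 + 7 * 1440].sum() / 1440.0
                assert row["camera_days"] == pytest.approx(expect, abs=1e-9)

    def test_effort_conservation(self):
        log = pd.DataFrame({"location": ["L1", "L2"],
                            "start": ["2020-01-06", "2020-01-20 06:00"],
                            "end": ["2020-02-14", "2020-03-01"]})
        eff = compute_effort(log, self.WEEKS)
        total = eff.groupby("location")["camera_days"].sum()
        assert total["L1"] == pytest.approx(39.0)
        assert total["L2"] == pytest.approx(40.75)


class TestWeeklyCounts:
    WEEKS = WeekScheme(anchor=datetime.date(2020, 1, 6))

    def _effort(self, weeks=(0, 1)):
        return pd.DataFrame({"location": "L1", "week": list(weeks),
                             "camera_days": [7.0] * len(weeks)})

    def test_group_sizes_sum(self):
        det = make_detections(["2020-01-06 08:00", "2020-01-06 12:00"],
                              counts=[3, 2])
        vis = collapse_visits(det, gap=GAP)
        tab = weekly_counts(vis, self._effort(), self.WEEKS)
        assert tab.loc[tab["week"] == 0, "y"].iloc[0] == 5

    def test_visit_count_mode(self):
        det = make_detections(["2020-01-06 08:00", "2020-01-06 12:00"],
                              counts=[3, 2])
        vis = collapse_visits(det, gap=GAP)
        tab = weekly_counts(vis, self._effort(), self.WEEKS,
                            count_mode="visits")
        assert tab.loc[tab["week"] == 0, "y"].iloc[0] == 2

    def test_structural_zero_rows_present(self):
        det = make_detections(["2020-01-06 08:00"])
        vis = collapse_visits(det, gap=GAP)
        tab = weekly_counts(vis, self._effort(weeks=(0, 1)), self.WEEKS)
        wk1 = tab[tab["week"] == 1]
        assert len(wk1) == 1 and wk1["y"].iloc[0] == 0

    def test_zero_effort_weeks_excluded(self):
        det = make_detections(["2020-01-06 08:00"])
        vis = collapse_visits(det, gap=GAP)
        eff = pd.DataFrame({"location": "L1", "week": [0, 1],
                            "camera_days": [7.0, 0.0]})
        tab = weekly_counts(vis, eff, self.WEEKS)
        assert set(tab["week"]) == {0}

    def test_visit_without_effort_is_error(self):
        det = make_detections(["2020-01-20 08:00"])  # week 2, not logged
        vis = collapse_visits(det, gap=GAP)
        with pytest.raises(EffortInconsistencyError, match="week 2"):
            weekly_counts(vis, self._effort(), self.WEEKS)

    def test_matches_generator_bookkeeping(self, small_dataset):
        ds = small_dataset
        vis = collapse_visits(ds.detections, gap=GAP)
        eff = compute_effort(ds.camera_log, ds.weeks)
        tab = weekly_counts(vis, eff, ds.weeks)
        merged = tab.merge(ds.counts, on=["location", "week", "species"],
                           how="outer", suffixes=("_got", "_want"))
        got = merged["y_got"].fillna(0)
        want = merged["y_want"].fillna(0)
        assert (got == want).all()


class TestWeekScheme:
    def test_site_start_anchor(self):
        log = pd.DataFrame({"location": ["L1"], "start": ["2020-01-08"],
                            "end": ["2020-02-01"]})
        ws = week_scheme_from_log(log, mode="site-start")
        assert ws.anchor == datetime.date(2020, 1, 8)
        assert ws.week_index("2020-01-08 00:00") == 0
        assert ws.week_index("2020-01-14 23:59") == 0
        assert ws.week_index("2020-01-15 00:00") == 1

    def test_iso_anchor_is_monday(self):
        log = pd.DataFrame({"location": ["L1"], "start": ["2020-01-08"],
                            "end": ["2020-02-01"]})
        ws = week_scheme_from_log(log, mode="iso")
        assert ws.anchor.weekday() == 0
        assert ws.anchor == datetime.date(2020, 1, 6)

    def test_month_attribution_uses_week_start(self):
        ws = WeekScheme(anchor=datetime.date(2020, 1, 29))
        assert ws.month_of_week(0) == 1   # week starts Jan 29
        assert ws.month_of_week(1) == 2
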