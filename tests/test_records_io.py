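"""Record ingest, independence filtering, effort and detection histories."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from siteuse import (DetectionHistory, OccasionGrid, build_detection_history,
                     compute_effort, filter_independent, read_records,
                     tabulate_by_zone)
from siteuse.records_io import RowParseError, SchemaError, StationInfo

from conftest import make_station, rec


# ---------------------------------------------------------------- read_records

def test_read_records_empty_file(tmp_path):
    p = tmp_path / "r.csv"
    p.write_text("station_id,species,timestamp\n")
    assert read_records(p) == []


def test_read_records_sorted(tmp_path):
    p = tmp_path / "r.csv"
    p.write_text(
        "station_id,species,timestamp\n"
        "s2,leopard,2015-06-03T10:00:00\n"
        "s1,leopard,2015-06-04T10:00:00\n"
        "s1,leopard,2015-06-02T09:00:00\n"
    )
    out = read_records(p)
    assert [(r.station_id, str(r.timestamp.date())) for r in out] == [
        ("s1", "2015-06-02"), ("s1", "2015-06-04"), ("s2", "2015-06-03")]


def test_read_records_bad_timestamp_names_row(tmp_path):
    p = tmp_path / "r.csv"
    p.write_text(
        "station_id,species,timestamp\n"
        "s1,leopard,2015-06-02T09:00:00\n"
        "s1,leopard,not-a-date\n"
    )
    with pytest.raises(RowParseError) as err:
        read_records(p)
    assert "3" in str(err.value)  # file line number of the bad row
    assert len(read_records(p, permissive=True)) == 1


def test_read_records_missing_column(tmp_path):
    p = tmp_path / "r.csv"
    p.write_text("station,species,timestamp\ns1,leopard,2015-06-02\n")
    with pytest.raises(SchemaError):
        read_records(p)
    # a schema map fixes it
    assert len(read_records(p, schema={"station_id": "station"})) == 1


# ---------------------------------------------------------- filter_independent

def test_filter_single_record_retained():
    r = [rec("s1", "leopard", "2015-06-01T10:00")]
    assert filter_independent(r) == r


def test_filter_chains_to_previously_retained():
    # gaps 3 and 4 min from neighbours, but 7 min from the retained record
    recs = [rec("s1", "leopard", f"2015-06-01T10:{m:02d}") for m in (0, 3, 7)]
    kept = filter_independent(recs)
    assert [r.timestamp.minute for r in kept] == [0, 7]


def test_filter_strict_at_exact_window():
    recs = [rec("s1", "leopard", "2015-06-01T10:00"),
            rec("s1", "leopard", "2015-06-01T10:05")]
    assert [r.timestamp.minute for r in filter_independent(recs)] == [0]


def test_filter_groups_by_station_and_species():
    recs = [rec("s1", "leopard", "2015-06-01T10:00"),
            rec("s1", "impala", "2015-06-01T10:01"),
            rec("s2", "leopard", "2015-06-01T10:02")]
    assert len(filter_independent(recs)) == 3


def test_filter_negative_window_rejected():
    with pytest.raises(ValueError):
        filter_independent([], window_minutes=-1)


@given(minutes=st.lists(st.integers(0, 600), min_size=1, max_size=40),
       window=st.integers(0, 30))
@hsettings(max_examples=80, deadline=None, derandomize=True)
def test_filter_idempotent_and_monotone(minutes, window):
    recs = [rec("s1", "leopard", pd.Timestamp("2015-06-01") + pd.Timedelta(minutes=m))
            for m in sorted(set(minutes))]
    once = filter_independent(recs, window)
    assert filter_independent(once, window) == once
    wider = filter_independent(recs, window + 5)
    assert len(wider) <= len(once)


# -------------------------------------------------------------- compute_effort

def test_effort_window_spanning_two_occasions(grid4):
    st_ = make_station(windows=[(date(2015, 6, 1), date(2015, 6, 15))])
    row = compute_effort([st_], grid4)[0]
    assert row.tolist() == [7, 7, 0, 0]


def test_effort_partial_occasion(grid4):
    st_ = make_station(windows=[(date(2015, 6, 1), date(2015, 6, 4))])
    assert compute_effort([st_], grid4)[0].tolist() == [3, 0, 0, 0]


def test_effort_two_disjoint_windows_one_occasion(grid4):
    st_ = make_station(windows=[(date(2015, 6, 1), date(2015, 6, 3)),
                                (date(2015, 6, 4), date(2015, 6, 8))])
    # day-by-day enumeration oracle
    active = [date(2015, 6, 1) + timedelta(days=k) for k in range(40)
              if any(s <= date(2015, 6, 1) + timedelta(days=k) < e
                     for s, e in st_.active_windows)]
    per_occ = [sum(1 for d in active if grid4.occasion_bounds(j)[0] <= d <
                   grid4.occasion_bounds(j)[1]) for j in range(4)]
    assert compute_effort([st_], grid4)[0].tolist() == per_occ
    assert per_occ[0] == 6


def test_effort_empty_windows_warns(grid4):
    with pytest.warns(UserWarning):
        eff = compute_effort([make_station()], grid4)
    assert eff.sum() == 0


def test_effort_conserves_window_days(grid4):
    st_ = make_station(windows=[(date(2015, 6, 3), date(2015, 6, 20))])
    eff = compute_effort([st_], grid4)
    assert eff.sum() == st_.total_active_days == 17


def test_effort_window_outside_grid_raises(grid4):
    st_ = make_station(windows=[(date(2015, 5, 1), date(2015, 6, 10))])
    with pytest.raises(ValueError):
        compute_effort([st_], grid4)


# --------------------------------------------------- build_detection_history

def full_station(sid="s1", **kw):
    return make_station(sid, windows=[(date(2015, 6, 1), date(2015, 6, 29))], **kw)


def test_history_no_records_all_zero(grid4):
    h = build_detection_history([], [full_station()], grid4)
    assert np.all(h.y == 0) and h.effort_days.sum() == 28


def test_history_binarizes_multiple_records(grid4):
    recs = [rec("s1", "leopard", f"2015-06-01T0{k}:00") for k in range(3)]
    h = build_detection_history(recs, [full_station()], grid4)
    assert h.y[0].tolist() == [1, 0, 0, 0]


def test_history_record_in_zero_effort_occasion_raises(grid4):
    st_ = make_station(windows=[(date(2015, 6, 1), date(2015, 6, 8))])
    with pytest.raises(ValueError, match="zero-effort"):
        build_detection_history([rec("s1", "leopard", "2015-06-20T10:00")],
                                [st_], grid4)


def test_history_orphan_station_raises(grid4):
    with pytest.raises(ValueError, match="ghost"):
        build_detection_history([rec("ghost", "leopard", "2015-06-02T10:00")],
                                [full_station()], grid4)


def test_history_invariant_enforced(grid4):
    y = np.zeros((1, 4))
    effort = np.array([[7, 7, 0, 7]])
    with pytest.raises(ValueError):
        DetectionHistory(["s1"], y, effort, grid4)  # 0 where effort==0 is invalid


def test_history_csv_roundtrip(tmp_path, grid4):
    st_ = make_station(windows=[(date(2015, 6, 1), date(2015, 6, 15))])
    h = build_detection_history([rec("s1", "leopard", "2015-06-02T10:00")], [st_], grid4)
    p = tmp_path / "h.csv"
    h.to_csv(p)
    assert "NA" in p.read_text()
    h2 = DetectionHistory.from_csv(p, h.effort_days, grid4)
    np.testing.assert_array_equal(h.y, h2.y)


# ------------------------------------------------------------ tabulate_by_zone

def test_tabulate_by_zone_hand_count(grid4):
    stations = [
        full_station("p1", zone="national_park"),
        full_station("p2", zone="national_park"),
        full_station("w1", zone="wma"),
        full_station("v1", zone="village_land"),
    ]
    recs = [rec("p1", "leopard", "2015-06-02T10:00"),
            rec("p1", "leopard", "2015-06-02T11:00"),
            rec("w1", "leopard", "2015-06-09T10:00")]
    h = build_detection_history(recs, stations, grid4)
    t = tabulate_by_zone(h, recs, stations)
    assert t.loc["national_park"].tolist() == [2, 1, 2, 56]
    assert t.loc["wma"].tolist() == [1, 1, 1, 28]
    assert t.loc["village_land"].tolist() == [1, 0, 0, 28]
    # conservation: zone tallies add up to the totals
    assert t["n_stations"].sum() == len(stations)
    assert t["effort_days"].sum() == h.effort_days.sum()
    # binarization: 1-cells never exceed independent events
    assert np.nansum(h.y) <= len(recs)


def test_station_validation():
    with pytest.raises(ValueError):
        StationInfo("s", 0, 0, "A", "national_park", "XX")
    with pytest.raises(ValueError):
        StationInfo("s", 0, 0, "A", "nowhere", "AT")
    with pytest.raises(ValueError):
        StationInfo("s", 0, 0, "A", "national_park", "AT",
                    [(date(2015, 6, 1), date(2015, 6, 10)),
                     (date(2015, 6, 5), date(2015, 6, 12))])
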