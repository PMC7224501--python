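import numpy as np
import pandas as pd
import pytest

from livestocknet.data_io import (
    DialectError, MovementTable, NodeListError, ProvenanceCounters,
    filter_movements, read_edge_list, read_node_list, split_survey_entry,
    split_survey_entries, summarize_movements, write_movement_table,
)

EDGE_HEADER = "from,to,fromc,toc,dmonth,type,weight,transp,intl\n"


def write_edges(tmp_path, rows, name="edges.csv"):
    path = tmp_path / name
    path.write_text(EDGE_HEADER + "".join(r + "\n" for r in rows))
    return path


class TestReadEdgeList:
    def test_parses_and_normalizes_categories(self, tmp_path):
        path = write_edges(tmp_path, [
            "A,B,C1,C2,2013-05,Cattle,12.5,Truck,true",
            "B,C,C2,C2,2014-11,SHEEP,3,on foot,false",
        ])
        table = read_edge_list(path)
        assert len(table) == 2
        assert list(table.records["livestock_type"]) == ["cattle", "sheep"]
        assert list(table.records["transport"]) == ["vehicle", "foot"]
        assert list(table.records["international"]) == [True, False]
        assert table.records["month"].iloc[0] == pd.Period("2013-05", "M")

    def test_empty_file_gives_empty_table(self, tmp_path):
        table = read_edge_list(write_edges(tmp_path, []))
        assert len(table) == 0
        assert table.counters.entries_read == 0
        assert table.counters.total_dropped == 0

    def test_bad_month_and_bad_value_are_counted(self, tmp_path):
        path = write_edges(tmp_path, [
            "A,B,C1,C2,notadate,cattle,5,vehicle,true",
            "A,B,C1,C2,2013-05,cattle,-1,vehicle,true",
            "A,B,C1,C2,2013-05,unicorn,5,vehicle,true",
            "A,B,C1,C2,2013-05,cattle,5,vehicle,true",
        ])
        table = read_edge_list(path)
        assert len(table) == 1
        assert table.counters.dropped_bad_month == 1
        assert table.counters.dropped_bad_value == 2
        table.check_conservation()

    def test_international_recomputed_and_conflicts_counted(self, tmp_path):
        path = write_edges(tmp_path, [
            "A,B,C1,C2,2013-05,cattle,5,vehicle,false",  # conflicting flag
        ])
        table = read_edge_list(path)
        assert bool(table.records["international"].iloc[0]) is True
        assert table.counters.intl_flag_overridden == 1

    def test_unresolvable_column_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(DialectError):
            read_edge_list(path)


class TestReadNodeList:
    def test_reads_and_validates_coordinates(self, tmp_path):
        path = tmp_path / "nodes.csv"
        path.write_text("name,cid,lat,lon\nA,C1,0,0\nB,C2,95,3\nC,C1,10,-1\n")
        nodes = read_node_list(path)
        # (0, 0) is boundary-legal, latitude 95 is rejected
        assert list(nodes.index) == ["A", "C"]
        assert nodes.attrs["rejected_rows"] == 1

    def test_duplicate_code_raises_naming_it(self, tmp_path):
        path = tmp_path / "nodes.csv"
        path.write_text("name,cid,lat,lon\nA,C1,1,1\nA,C2,2,2\n")
        with pytest.raises(NodeListError, match="A"):
            read_node_list(path)


class TestSplitSurveyEntry:
    @staticmethod
    def entry(origin, survey, dest):
        return {"origin_market": origin, "survey_market": survey,
                "destination_market": dest, "month": pd.Period("2014-02", "M"),
                "livestock_type": "cattle", "heads": 4.0,
                "transport": "vehicle"}

    def test_distinct_triplet_gives_two_legs(self):
        recs = split_survey_entry(self.entry("A", "S", "B"))
        assert [(r["from_market"], r["to_market"]) for r in recs] \
            == [("A", "S"), ("S", "B")]
        assert all(r["heads"] == 4.0 for r in recs)

    def test_origin_equal_to_survey_gives_one_leg(self):
        recs = split_survey_entry(self.entry("S", "S", "B"))
        assert [(r["from_market"], r["to_market"]) for r in recs] == [("S", "B")]

    def test_round_trip_through_survey_gives_two_legs_no_self_loop(self):
        recs = split_survey_entry(self.entry("A", "S", "A"))
        assert [(r["from_market"], r["to_market"]) for r in recs] \
            == [("A", "S"), ("S", "A")]
        assert all(r["from_market"] != r["to_market"] for r in recs)

    def test_missing_endpoint_leg_is_emitted_for_later_filtering(self):
        recs = split_survey_entry(self.entry(None, "S", "B"))
        assert [(r["from_market"], r["to_market"]) for r in recs] \
            == [(None, "S"), ("S", "B")]


class TestFilterMovements:
    def make_table(self):
        entries = pd.DataFrame({
            "origin_market": ["A", "A", pd.NA, "S"],
            "survey_market": ["S", "S", "S", "S"],
            "destination_market": ["B", "Zz", "B", "S"],
            "month": pd.PeriodIndex(["2013-01"] * 4, freq="M"),
            "livestock_type": ["cattle"] * 4,
            "heads": [1.0, 2.0, 3.0, 4.0],
            "transport": ["vehicle"] * 4,
        })
        return split_survey_entries(entries)

    def test_incomplete_unmapped_and_self_loops_dropped_with_reasons(self):
        table = self.make_table()
        out = filter_movements(table, geolocatable={"A", "S", "B"})
        # entry 4 (S->S->S) emits nothing; the rest give 6 legs
        assert table.counters.records_created == 6
        assert table.counters.entries_unsplit == 1
        assert out.counters.dropped_incomplete == 1   # NA -> S leg
        assert out.counters.dropped_unmapped == 1     # S -> Zz leg
        assert out.counters.dropped_self_loop == 0
        assert len(out) == 4
        out.check_conservation()

    def test_self_loop_dropped(self):
        df = pd.DataFrame({
            "from_market": ["A", "B"], "to_market": ["A", "A"],
            "from_country": ["C1", "C1"], "to_country": ["C1", "C1"],
            "month": pd.PeriodIndex(["2013-01", "2013-02"], freq="M"),
            "livestock_type": ["cattle", "goat"], "heads": [1.0, 2.0],
            "transport": ["foot", "train"], "international": [False, False],
        })
        out = filter_movements(MovementTable(df), {"A", "B"})
        assert out.counters.dropped_self_loop == 1
        assert len(out) == 1


class TestSummaries:
    def test_percentages_partition_to_100(self, small_dataset):
        table, _ = small_dataset
        for dim in ("movement-type", "livestock", "transport",
                    "origin-country", "destination-country"):
            s = summarize_movements(table, dim)
            assert s["count"].sum() <= len(table)
            assert s["percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_single_record_is_100_percent(self):
        df = pd.DataFrame({
            "from_market": ["A"], "to_market": ["B"],
            "from_country": ["C1"], "to_country": ["C2"],
            "month": pd.PeriodIndex(["2013-01"], freq="M"),
            "livestock_type": ["goat"], "heads": [1.0],
            "transport": ["train"], "international": [True],
        })
        s = summarize_movements(MovementTable(df), "livestock")
        assert s.loc["goat", "percent"] == 100.0

    def test_empty_table_gives_explicit_empty_summary(self):
        table = MovementTable(pd.DataFrame(columns=[
            "from_market", "to_market", "from_country", "to_country",
            "month", "livestock_type", "heads", "transport", "international"]))
        s = summarize_movements(table, "livestock")
        assert s.empty

    def test_month_livestock_is_a_monthly_matrix(self, small_dataset):
        table, _ = small_dataset
        pivot = summarize_movements(table, "month-livestock")
        assert pivot.to_numpy().sum() == len(table)
        assert isinstance(pivot.index, pd.PeriodIndex)


def test_round_trip_write_then_read_is_identity(tmp_path, small_dataset):
    table, _ = small_dataset
    path = tmp_path / "canonical.csv"
    write_movement_table(table, path)
    back = read_edge_list(path, dialect={k: k for k in (
        "from_market", "to_market", "from_country", "to_country", "month",
        "livestock_type", "heads", "transport", "international")})
    assert len(back) == len(table)
    a = table.records.reset_index(drop=True)
    b = back.records.reset_index(drop=True)
    for col in ("from_market", "to_market", "livestock_type", "transport"):
        assert list(a[col]) == list(b[col])
    assert np.allclose(a["heads"], b["heads"])
    assert list(a["month"]) == list(b["month"])
    assert list(a["international"]) == list(b["international"])


def test_conservation_invariant_on_generated_data(small_dataset):
    table, _ = small_dataset
    c = table.counters
    assert c.records_created == len(table) + c.total_dropped
    table.check_conservation()
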