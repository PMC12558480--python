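import numpy as np
import pandas as pd
import pytest

from pvsignal.cases import DrugEventSet, extract_event_sets
from pvsignal.descriptives import (annual_counts, compute_tto,
                                   summarize_demographics, summarize_outcomes)


def make_events(meta_rows):
    cols = ["report_id", "sex", "age_years", "reporter", "country",
            "receipt_year", "event_date", "is_target"]
    meta = pd.DataFrame(meta_rows, columns=cols)
    empty = pd.DataFrame(columns=["report_id", "term", "term_norm"])
    return DrugEventSet(target_pairs=empty, background_pairs=empty,
                        target_report_ids=set(meta.loc[meta["is_target"],
                                                       "report_id"]),
                        report_meta=meta)


def row(rid, sex="F", age=60.0, reporter="physician", country="US",
        year=2017, event_date="20200105", target=True):
    return (rid, sex, age, reporter, country, year, event_date, target)


class TestDemographics:
    def test_sex_counts_and_percent(self):
        events = make_events([row("r1"), row("r2"), row("r3", sex="M")])
        tab = summarize_demographics(events)
        sex = tab[tab["category"] == "sex"].set_index("level")
        assert sex.loc["female", "count"] == 2
        assert sex.loc["female", "percent"] == pytest.approx(66.67, abs=0.01)
        assert sex.loc["male", "percent"] == pytest.approx(33.33, abs=0.01)

    @pytest.mark.parametrize("age, bin_", [
        (60.0, "60-74"),          # bins are left-closed
        (59.999, "45-59"),
        (50.0, "45-59"),          # 5 DEC normalized upstream to 50 years
        (np.nan, "unknown"),
        (95.0, ">=90"),
    ])
    def test_age_binning(self, age, bin_):
        events = make_events([row("r1", age=age)])
        tab = summarize_demographics(events)
        ages = tab[tab["category"] == "age_years"].set_index("level")
        assert ages.loc[bin_, "count"] == 1

    def test_percents_sum_to_100_per_category(self):
        events = make_events([row(f"r{i}", sex=s, age=a)
                              for i, (s, a) in enumerate(
                                  [("F", 20), ("M", 50), ("UNK", np.nan),
                                   ("F", 70), ("M", 92)])])
        tab = summarize_demographics(events)
        for cat, sub in tab.groupby("category"):
            assert sub["percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_non_target_reports_excluded(self):
        events = make_events([row("r1"), row("r2", target=False)])
        tab = summarize_demographics(events)
        assert tab[tab["category"] == "sex"]["count"].sum() == 1


class TestOutcomes:
    def _outc(self):
        return pd.DataFrame({"report_id": ["r1", "r1", "r2"],
                             "outcome": ["HO", "DE", "HO"]})

    def test_per_code_policy(self):
        events = make_events([row("r1"), row("r2")])
        tab = summarize_outcomes(events, self._outc()).set_index("level")
        assert tab.loc["hospitalization", "count"] == 2
        assert tab.loc["death", "count"] == 1
        assert tab.loc["hospitalization", "percent"] == pytest.approx(66.67, abs=0.01)

    def test_worst_outcome_policy(self):
        events = make_events([row("r1"), row("r2")])
        tab = summarize_outcomes(events, self._outc(), policy="worst").set_index("level")
        assert tab.loc["death", "count"] == 1      # DE outranks HO for r1
        assert tab.loc["hospitalization", "count"] == 1
        assert tab.loc["death", "percent"] == pytest.approx(50.0)

    def test_duplicate_codes_count_once_per_report(self):
        events = make_events([row("r1")])
        outc = pd.DataFrame({"report_id": ["r1", "r1"], "outcome": ["HO", "HO"]})
        tab = summarize_outcomes(events, outc).set_index("level")
        assert tab.loc["hospitalization", "count"] == 1

    def test_unknown_codes_fall_under_other(self):
        events = make_events([row("r1")])
        outc = pd.DataFrame({"report_id": ["r1"], "outcome": ["ZZ"]})
        tab = summarize_outcomes(events, outc).set_index("level")
        assert tab.loc["other serious", "count"] == 1


class TestTto:
    def _fixture(self, event_dates, start_dates):
        n = len(event_dates)
        events = make_events([row(f"r{i}", event_date=event_dates[i])
                              for i in range(n)])
        drug = pd.DataFrame({"report_id": [f"r{i}" for i in range(n)],
                             "drug_seq": [1] * n, "role": ["PS"] * n,
                             "drugname": ["CINACALCET"] * n,
                             "active_ingredient": [None] * n})
        ther = pd.DataFrame({"report_id": [f"r{i}" for i in range(n)],
                             "drug_seq": [1] * n,
                             "start_date": start_dates,
                             "end_date": [""] * n})
        return events, ther, drug

    @pytest.mark.parametrize("start, event, days, bin_", [
        ("20200101", "20200105", 4, "<7"),
        ("20200101", "20200401", 91, ">=60"),
        ("20200101", "20200110", 9, "7-28"),
        ("20200101", "20200215", 45, "28-60"),
    ])
    def test_day_difference_and_bins(self, start, event, days, bin_):
        events, ther, drug = self._fixture([event], [start])
        tto = compute_tto(events, ther, drug)
        assert tto.records.loc[0, "days"] == days
        assert tto.records.loc[0, "bin"] == bin_

    def test_median_iqr_linear_interpolation(self):
        """Known onsets {2, 8, 80} -> median 8, interpolated quartiles (5, 44)."""
        events, ther, drug = self._fixture(
            ["20200103", "20200109", "20200321"], ["20200101"] * 3)
        tto = compute_tto(events, ther, drug)
        assert sorted(tto.records["days"].dropna()) == [2, 8, 80]
        assert tto.median == 8.0
        assert (tto.q1, tto.q3) == (5.0, 44.0)
        bins = tto.bin_table().set_index("level")
        assert bins.loc["<7", "count"] == 1
        assert bins.loc["7-28", "count"] == 1
        assert bins.loc[">=60", "count"] == 1

    def test_partial_or_missing_dates_are_unknown(self):
        events, ther, drug = self._fixture(["202001", "20200105", ""],
                                           ["20200101", "2020", "20200101"])
        tto = compute_tto(events, ther, drug)
        assert tto.n_known == 0
        assert (tto.records["bin"] == "unknown").all()

    def test_negative_tto_tracked_not_counted(self):
        events, ther, drug = self._fixture(["20200101"], ["20200301"])
        tto = compute_tto(events, ther, drug)
        assert tto.n_negative == 1 and tto.n_known == 0

    def test_bins_plus_unknown_cover_all_target_reports(self):
        events, ther, drug = self._fixture(
            ["20200105", "202002", ""], ["20200101", "20200101", "20200101"])
        tto = compute_tto(events, ther, drug)
        assert int(tto.bin_table()["count"].sum()) == 3


class TestAnnualCounts:
    def test_counts_by_receipt_year(self):
        events = make_events([row("r1", year=2017), row("r2", year=2017),
                              row("r3", year=2018)])
        tab = annual_counts(events).set_index("level")
        assert tab.loc["2017", "count"] == 2
        assert tab.loc["2018", "count"] == 1

    def test_empty_and_unknown(self):
        assert annual_counts(make_events([])).empty
        tab = annual_counts(make_events([row("r1", year=None)])).set_index("level")
        assert tab.loc["unknown", "count"] == 1
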