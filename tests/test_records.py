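import io
import math

import pytest
from hypothesis import given, settings, strategies as st

from recordevo import (
    AnnualBestSeries,
    MarkParseError,
    PanelError,
    compare_spans,
    improvement_percent,
    parse_mark,
    rank_events,
    read_annual_bests,
    write_annual_bests,
)
from recordevo.records import format_mark
from recordevo.simulate import default_panel_spec, simulate_panel


class TestParseMark:
    @pytest.mark.parametrize(
        "text,unit,expected",
        [
            ("8.95", "meters", 8.95),
            ("9.58", "seconds", 9.58),
            ("1:45.20", "seconds", 105.20),
            ("2:03:38", "seconds", 7418.0),
            ("0:59.9", "seconds", 59.9),
            (" 10.0 ", "seconds", 10.0),
        ],
    )
    def test_dialects(self, text, unit, expected):
        assert parse_mark(text, unit) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "text,unit",
        [
            ("", "seconds"),
            ("abc", "seconds"),
            ("1:2:3:4", "seconds"),
            ("-9.5", "seconds"),
            ("1:-10", "seconds"),
            ("0", "seconds"),
            ("0.0", "meters"),
            ("1:30", "meters"),  # colon dialect invalid for distances
        ],
    )
    def test_rejects_malformed(self, text, unit):
        with pytest.raises(MarkParseError):
            parse_mark(text, unit)

    def test_error_names_offending_token(self):
        with pytest.raises(MarkParseError, match="xx"):
            parse_mark("1:xx", "seconds")

    @given(st.floats(min_value=1e-6, max_value=1e5, allow_nan=False))
    @settings(max_examples=100, derandomize=True)
    def test_format_parse_roundtrip(self, value):
        assert parse_mark(format_mark(value), "meters") == value


class TestSeriesInvariants:
    def test_rejects_nonpositive_mark(self):
        with pytest.raises(PanelError, match="non-positive"):
            AnnualBestSeries("e", "minimize", "seconds", {1992: 0.0})

    def test_rejects_year_outside_range(self):
        with pytest.raises(PanelError, match="1970"):
            AnnualBestSeries("e", "minimize", "seconds", {1970: 10.0})

    def test_rejects_bad_direction_and_unit(self):
        with pytest.raises(PanelError):
            AnnualBestSeries("e", "sideways", "seconds", {1992: 1.0})
        with pytest.raises(PanelError):
            AnnualBestSeries("e", "minimize", "furlongs", {1992: 1.0})

    def test_missing_year_error_names_event_and_year(self, sprint_series):
        with pytest.raises(PanelError, match="100m.*2001"):
            sprint_series.mark(2001)


class TestCatalog:
    def test_default_roster(self, catalog):
        assert len(catalog) == 24
        assert [e.index for e in catalog.entries] == list(range(1, 25))
        assert catalog.event_ids[0] == "100m"
        assert catalog.event_ids[-1] == "triple_jump"
        assert catalog["marathon"].category == "marathon"
        assert catalog["long_jump"].direction == "maximize"
        assert catalog["50m_free"].category == "swim"

    def test_unknown_event(self, catalog):
        with pytest.raises(PanelError, match="pole_vault"):
            catalog["pole_vault"]


class TestPanelIO:
    def test_toy_table(self, catalog):
        csv = "event_id,year,mark\n100m,1992,9.93\n100m,1993,9.87\n100m,1994,9.85\n"
        panel = read_annual_bests(io.StringIO(csv), catalog)
        assert set(panel) == {"100m"}
        assert panel["100m"].marks == {1992: 9.93, 1993: 9.87, 1994: 9.85}
        assert panel["100m"].direction == "minimize"

    def test_marathon_mark_dialect(self, catalog):
        csv = "event_id,year,mark\nmarathon,1992,2:08:01\n"
        panel = read_annual_bests(io.StringIO(csv), catalog)
        assert panel["marathon"].mark(1992) == 2 * 3600 + 8 * 60 + 1

    def test_duplicate_row_names_row_number(self, catalog):
        csv = "event_id,year,mark\n100m,1992,9.93\n100m,1992,9.90\n"
        with pytest.raises(PanelError, match="row 3"):
            read_annual_bests(io.StringIO(csv), catalog)

    def test_unknown_event_id(self, catalog):
        csv = "event_id,year,mark\npole_vault,1992,6.05\n"
        with pytest.raises(PanelError, match="row 2.*pole_vault"):
            read_annual_bests(io.StringIO(csv), catalog)

    def test_unparseable_mark_names_row(self, catalog):
        csv = "event_id,year,mark\n100m,1992,fast\n"
        with pytest.raises(PanelError, match="row 2"):
            read_annual_bests(io.StringIO(csv), catalog)

    def test_unit_conflict(self, catalog):
        csv = "event_id,year,mark,unit\n100m,1992,9.93,meters\n"
        with pytest.raises(PanelError, match="unit"):
            read_annual_bests(io.StringIO(csv), catalog)

    def test_write_read_roundtrip_identity(self, catalog, default_panel, tmp_path):
        """Write-then-read is the identity on (event, year, mark) triples
        to full float precision, on a full 24x27 synthetic panel."""
        path = tmp_path / "panel.csv"
        write_annual_bests(default_panel, path)
        back = read_annual_bests(path, catalog)
        assert set(back) == set(default_panel)
        for event_id, series in default_panel.items():
            assert back[event_id].marks == series.marks


class TestImprovementPercent:
    def test_minimize_drop_is_positive(self):
        s = AnnualBestSeries("e", "minimize", "seconds", {1992: 100.0, 1993: 90.0})
        assert improvement_percent(s, 1992, 1993) == pytest.approx(10.0)

    def test_maximize_gain_is_positive(self):
        s = AnnualBestSeries("e", "maximize", "meters", {1992: 8.00, 1993: 8.40})
        assert improvement_percent(s, 1992, 1993) == pytest.approx(5.0)

    def test_equal_marks_zero(self):
        s = AnnualBestSeries("e", "minimize", "seconds", {1992: 10.0, 1993: 10.0})
        assert improvement_percent(s, 1992, 1993) == 0.0

    def test_worsening_is_negative_growth(self):
        s = AnnualBestSeries("e", "maximize", "meters", {1992: 8.40, 1993: 8.00})
        assert improvement_percent(s, 1992, 1993) < 0

    @given(
        base=st.floats(min_value=1.0, max_value=1e4),
        target=st.floats(min_value=1.0, max_value=1e4),
    )
    @settings(max_examples=100, derandomize=True)
    def test_direction_symmetry(self, base, target):
        """The same relative move reports positive improvement for a
        shrinking time and for a growing distance alike."""
        tmin = AnnualBestSeries("t", "minimize", "seconds", {1992: base, 1993: target})
        dmax = AnnualBestSeries("d", "maximize", "meters", {1992: target, 1993: base})
        a = improvement_percent(tmin, 1992, 1993)
        b = improvement_percent(dmax, 1992, 1993)
        assert (a > 0) == (base > target)
        assert (b > 0) == (base > target)


class TestCompareSpans:
    def test_constant_series_all_zero(self):
        marks = {y: 10.0 for y in range(1992, 2019)}
        panel = {"e": AnnualBestSeries("e", "minimize", "seconds", marks)}
        df = compare_spans(panel, (1992, 2005), (2005, 2018))
        assert (df.drop(columns="mean_change") == 0).all().all()
        assert df.loc["e", "mean_change"] == 0.0

    def test_hand_computed_mean(self):
        # pairs: 1992->1994 (+10%), 1993->1995 (+20%)
        marks = {1992: 100.0, 1993: 100.0, 1994: 90.0, 1995: 80.0}
        panel = {"e": AnnualBestSeries("e", "minimize", "seconds", marks)}
        df = compare_spans(panel, (1992, 1993), (1994, 1995))
        assert df.loc["e", "mean_change"] == pytest.approx(15.0)

    def test_reversed_span_pairs_backwards(self):
        marks = {1992: 100.0, 1993: 100.0, 1994: 95.0, 1995: 80.0}
        panel = {"e": AnnualBestSeries("e", "minimize", "seconds", marks)}
        df = compare_spans(panel, (1992, 1993), (1995, 1994))
        # pairs: 1992->1995 (+20%), 1993->1994 (+5%)
        assert df.loc["e", "1992->1995"] == pytest.approx(20.0)
        assert df.loc["e", "mean_change"] == pytest.approx(12.5)

    def test_unequal_spans_rejected(self, default_panel):
        with pytest.raises(PanelError, match="lengths differ"):
            compare_spans(default_panel, (1992, 2000), (2005, 2018))

    def test_mean_change_grows_with_drift(self):
        """Regenerating the same panel at a larger drift raises the mean
        span-to-span improvement."""
        from recordevo import EventSpec, PanelSpec, simulate_panel

        def panel(drift):
            spec = PanelSpec(
                events=[EventSpec("e", "minimize", "seconds", 100.0, 0.5, drift)],
                years=(1992, 2018), seed=42,
            )
            return simulate_panel(spec)

        low = compare_spans(panel(0.05)).loc["e", "mean_change"]
        high = compare_spans(panel(0.30)).loc["e", "mean_change"]
        assert high > low


class TestRankEvents:
    def test_single_event(self):
        marks = {y: 10.0 for y in range(1992, 2019)}
        panel = {"e": AnnualBestSeries("e", "minimize", "seconds", marks)}
        ranking = rank_events(compare_spans(panel))
        assert list(ranking["rank"]) == [1]

    def test_sorting_and_dense_ranks(self, catalog):
        import pandas as pd

        comparison = pd.DataFrame(
            {"mean_change": [5.0, 3.0, 7.0]},
            index=pd.Index(["a", "b", "c"], name="event_id"),
        )
        ranking = rank_events(comparison)
        assert list(ranking.index) == ["c", "a", "b"]
        assert list(ranking["rank"]) == [1, 2, 3]

    def test_ties_broken_by_catalog_index(self, catalog):
        import pandas as pd

        comparison = pd.DataFrame(
            {"mean_change": [2.0, 2.0]},
            index=pd.Index(["marathon", "100m"], name="event_id"),
        )
        ranking = rank_events(comparison, catalog)
        assert list(ranking.index) == ["100m", "marathon"]  # catalog order 1 < 7
        assert list(ranking["rank"]) == [1, 1]  # dense: shared rank

    def test_empty_rejected(self):
        import pandas as pd

        with pytest.raises(PanelError):
            rank_events(pd.DataFrame(columns=["mean_change"]))

    def test_planted_drift_order_recovered(self):
        """Noise-free panels with strictly ordered drifts rank exactly in
        drift order."""
        from recordevo import EventSpec, PanelSpec, simulate_panel

        drifts = {"a": 0.30, "b": 0.10, "c": 0.20}
        spec = PanelSpec(
            events=[
                EventSpec(e, "minimize", "seconds", 100.0, 0.0, d)
                for e, d in drifts.items()
            ],
            years=(1992, 2018), seed=0,
        )
        ranking = rank_events(compare_spans(simulate_panel(spec)))
        assert list(ranking.index) == ["a", "c", "b"]

    def test_output_is_permutation_attaining_max(self, default_panel, catalog):
        comparison = compare_spans(default_panel)
        ranking = rank_events(comparison, catalog)
        assert sorted(ranking.index) == sorted(comparison.index)
        top = ranking.index[0]
        assert comparison.loc[top, "mean_change"] == comparison["mean_change"].max()
        assert ranking["rank"].iloc[0] == 1
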