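"""Data model and I/O for annual-best performance panels.

The unit of observation is the *annual best*: the single best performance
achieved in one event within one calendar year.  A panel is a collection of
:class:`AnnualBestSeries`, one per event, typically 24 events x 27 years
(1992-2018).  Events are either *minimize* type (timed events: track,
swimming — a smaller mark is better) or *maximize* type (jumps — a larger
mark is better).

This module also implements the record-evolution statistics: signed percent
improvement between two years, paired-span comparisons, and event rankings
by mean improvement.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

MINIMIZE = "minimize"
MAXIMIZE = "maximize"
SECONDS = "seconds"
METERS = "meters"

DEFAULT_YEAR_RANGE = (1992, 2018)


class MarkParseError(ValueError):
    """A performance-mark string could not be parsed."""


class PanelError(ValueError):
    """A panel or series violates its invariants."""


# ---------------------------------------------------------------------------
# mark parsing
# ---------------------------------------------------------------------------

def parse_mark(text: str, unit: str = SECONDS) -> float:
    """Parse a performance mark string into SI units (seconds or meters).

    Accepted dialects:

    * plain decimal: ``"8.95"``
    * minutes:seconds: ``"1:45.20"`` -> 105.20 s
    * hours:minutes:seconds: ``"2:03:38"`` -> 7418.0 s

    The colon dialects are only meaningful for timed marks; distances must
    be plain decimals.

    Raises
    ------
    MarkParseError
        If the string is malformed, has negative components, or the value
        is not strictly positive.
    """
    if not isinstance(text, str):
        raise MarkParseError(f"mark must be a string, got {type(text).__name__}")
    text = text.strip()
    if not text:
        raise MarkParseError("empty mark string")
    parts = text.split(":")
    if len(parts) > 3:
        raise MarkParseError(f"too many ':' components in mark {text!r}")
    if len(parts) > 1 and unit != SECONDS:
        raise MarkParseError(f"colon-separated mark {text!r} is not a valid {unit} value")
    try:
        numbers = [float(p) for p in parts]
    except ValueError:
        bad = next(p for p in parts if not _is_float(p))
        raise MarkParseError(f"malformed component {bad!r} in mark {text!r}") from None
    if any(n < 0 for n in numbers):
        bad = next(p for p in parts if float(p) < 0)
        raise MarkParseError(f"negative component {bad!r} in mark {text!r}")
    if len(parts) == 1:
        value = numbers[0]
    elif len(parts) == 2:  # M:SS.ff
        value = 60.0 * numbers[0] + numbers[1]
    else:  # H:MM:SS
        value = 3600.0 * numbers[0] + 60.0 * numbers[1] + numbers[2]
    if value <= 0:
        raise MarkParseError(f"mark {text!r} is not strictly positive")
    return value


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def format_mark(value: float) -> str:
    """Render a mark with full float precision (round-trips via parse_mark)."""
    return repr(float(value))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AnnualBestSeries:
    """One event's annual best marks over a range of years.

    Parameters
    ----------
    event_id : str
        Short unique key, e.g. ``"100m"`` or ``"200m_back"``.
    direction : {"minimize", "maximize"}
        Whether a better performance is a smaller (times) or larger
        (distances/heights) mark.
    unit : {"seconds", "meters"}
    marks : dict
        Mapping year -> strictly positive annual-best mark in SI units.
    year_range : (int, int)
        Inclusive range the years must fall in.
    """

    event_id: str
    direction: str
    unit: str
    marks: dict[int, float] = field(default_factory=dict)
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE

    def __post_init__(self) -> None:
        if self.direction not in (MINIMIZE, MAXIMIZE):
            raise PanelError(f"{self.event_id}: unknown direction {self.direction!r}")
        if self.unit not in (SECONDS, METERS):
            raise PanelError(f"{self.event_id}: unknown unit {self.unit!r}")
        lo, hi = self.year_range
        for year, mark in self.marks.items():
            if not (lo <= year <= hi):
                raise PanelError(
                    f"{self.event_id}: year {year} outside declared range {lo}-{hi}"
                )
            if not mark > 0:
                raise PanelError(f"{self.event_id}: non-positive mark {mark} in {year}")

    @property
    def years(self) -> list[int]:
        return sorted(self.marks)

    def mark(self, year: int) -> float:
        try:
            return self.marks[year]
        except KeyError:
            raise PanelError(f"{self.event_id}: no mark for year {year}") from None

    def internal_mark(self, year: int) -> float:
        """Mark on the internal maximize scale (times negated)."""
        m = self.mark(year)
        return -m if self.direction == MINIMIZE else m


@dataclass(frozen=True)
class CatalogEntry:
    index: int
    event_id: str
    name: str
    category: str
    direction: str
    unit: str


class EventCatalog:
    """Ordered roster of events with display names and category labels.

    The packaged default catalog lists the 24 men's track, field and
    swimming events in legend order (1 = 100m sprint ... 24 = triple jump).
    """

    CATEGORIES = frozenset(
        {"sprint", "middle/long running", "marathon", "hurdles", "jump", "swim"}
    )

    def __init__(self, entries: Sequence[CatalogEntry]):
        ids = [e.event_id for e in entries]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate event_id in catalog")
        self.entries: list[CatalogEntry] = sorted(entries, key=lambda e: e.index)
        self._by_id = {e.event_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, event_id: str) -> bool:
        return event_id in self._by_id

    def __getitem__(self, event_id: str) -> CatalogEntry:
        try:
            return self._by_id[event_id]
        except KeyError:
            raise PanelError(f"unknown event_id {event_id!r}") from None

    @property
    def event_ids(self) -> list[str]:
        return [e.event_id for e in self.entries]

    def index_of(self, event_id: str) -> int:
        return self[event_id].index

    @classmethod
    def from_csv(cls, source) -> "EventCatalog":
        df = pd.read_csv(source)
        required = {"index", "event_id", "name", "category", "direction", "unit"}
        missing = required - set(df.columns)
        if missing:
            raise PanelError(f"catalog missing columns: {sorted(missing)}")
        entries = [
            CatalogEntry(
                int(r["index"]), str(r["event_id"]), str(r["name"]),
                str(r["category"]), str(r["direction"]), str(r["unit"]),
            )
            for _, r in df.iterrows()
        ]
        for e in entries:
            if e.category not in cls.CATEGORIES:
                raise PanelError(f"{e.event_id}: unknown category {e.category!r}")
        return cls(entries)


def load_default_catalog() -> EventCatalog:
    """Load the packaged 24-event roster."""
    ref = resources.files("recordevo").joinpath("data/event_catalog.csv")
    with ref.open("r", encoding="utf-8") as fh:
        catalog = EventCatalog.from_csv(fh)
    indices = [e.index for e in catalog.entries]
    if indices != list(range(1, len(indices) + 1)):
        raise PanelError("packaged catalog indices are not contiguous 1..n")
    return catalog


# ---------------------------------------------------------------------------
# panel I/O
# ---------------------------------------------------------------------------

def read_annual_bests(
    source,
    catalog: EventCatalog,
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE,
) -> dict[str, AnnualBestSeries]:
    """Read a panel from a CSV stream or path.

    Schema: header row with ``event_id,year,mark`` (an optional ``unit``
    column is accepted and checked against the catalog).  Marks may use any
    dialect accepted by :func:`parse_mark`.  Every event_id must be in the
    catalog; duplicate (event, year) pairs are an error.

    Returns a dict event_id -> :class:`AnnualBestSeries`, in catalog order.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_annual_bests(fh, catalog, year_range)
    reader = csv.DictReader(source)
    if reader.fieldnames is None or not {"event_id", "year", "mark"} <= set(reader.fieldnames):
        raise PanelError("panel CSV must have header columns event_id,year,mark")
    marks: dict[str, dict[int, float]] = {}
    for rownum, row in enumerate(reader, start=2):  # row 1 is the header
        event_id = (row["event_id"] or "").strip()
        if event_id not in catalog:
            raise PanelError(f"row {rownum}: unknown event_id {event_id!r}")
        entry = catalog[event_id]
        try:
            year = int(row["year"])
        except (TypeError, ValueError):
            raise PanelError(f"row {rownum}: bad year {row['year']!r}") from None
        try:
            value = parse_mark(row["mark"], entry.unit)
        except MarkParseError as exc:
            raise PanelError(f"row {rownum}: {exc}") from None
        if row.get("unit") not in (None, "", entry.unit):
            raise PanelError(
                f"row {rownum}: unit {row['unit']!r} conflicts with catalog "
                f"({entry.unit}) for {event_id}"
            )
        ev = marks.setdefault(event_id, {})
        if year in ev:
            raise PanelError(f"row {rownum}: duplicate entry for ({event_id}, {year})")
        ev[year] = value
    panel: dict[str, AnnualBestSeries] = {}
    for event_id in catalog.event_ids:
        if event_id in marks:
            entry = catalog[event_id]
            panel[event_id] = AnnualBestSeries(
                event_id, entry.direction, entry.unit, marks[event_id], year_range
            )
    return panel


def write_annual_bests(panel: Mapping[str, AnnualBestSeries], dest) -> None:
    """Write a panel in the ``event_id,year,mark,unit`` CSV schema.

    Marks are written with full float precision so that a write-then-read
    cycle is the identity on (event_id, year, mark) triples.
    """
    if isinstance(dest, (str, bytes)) or hasattr(dest, "__fspath__"):
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            write_annual_bests(panel, fh)
        return
    writer = csv.writer(dest, lineterminator="\n")
    writer.writerow(["event_id", "year", "mark", "unit"])
    for event_id, series in panel.items():
        for year in series.years:
            writer.writerow([event_id, year, format_mark(series.marks[year]), series.unit])


def panel_to_csv_string(panel: Mapping[str, AnnualBestSeries]) -> str:
    buf = io.StringIO()
    write_annual_bests(panel, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# record-evolution statistics
# ---------------------------------------------------------------------------

def improvement_percent(series: AnnualBestSeries, baseline_year: int, target_year: int) -> float:
    """Signed percent change from baseline_year to target_year.

    Positive = improvement, on the baseline mark's scale: for minimize
    events ``100*(base - target)/base``, for maximize events
    ``100*(target - base)/base``.  Negative values are "negative growth".
    """
    base = series.mark(baseline_year)
    target = series.mark(target_year)
    if series.direction == MINIMIZE:
        return 100.0 * (base - target) / base
    return 100.0 * (target - base) / base


DEFAULT_SPAN_A = (1992, 2005)
DEFAULT_SPAN_B = (2005, 2018)


def compare_spans(
    panel: Mapping[str, AnnualBestSeries],
    span_a: tuple[int, int] = DEFAULT_SPAN_A,
    span_b: tuple[int, int] = DEFAULT_SPAN_B,
) -> pd.DataFrame:
    """Paired-year percent changes between two equal-length year spans.

    The k-th year of ``span_a`` is paired with the k-th year of ``span_b``
    (defaults: 1992<->2005, ..., 2005<->2018, a fixed 13-year offset).
    Returns a DataFrame indexed by event_id with one column per year pair
    plus a ``mean_change`` column (arithmetic mean of the paired changes).
    """
    def span_years(span: tuple[int, int]) -> list[int]:
        lo, hi = span
        step = 1 if hi >= lo else -1  # reversed spans pair years backwards
        return list(range(lo, hi + step, step))

    years_a = span_years(span_a)
    years_b = span_years(span_b)
    if len(years_a) != len(years_b):
        raise PanelError(
            f"span lengths differ: {span_a} has {len(years_a)} years, "
            f"{span_b} has {len(years_b)}"
        )
    if not panel:
        raise PanelError("empty panel")
    columns = [f"{ya}->{yb}" for ya, yb in zip(years_a, years_b)]
    rows = {}
    for event_id, series in panel.items():
        rows[event_id] = [
            improvement_percent(series, ya, yb) for ya, yb in zip(years_a, years_b)
        ]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    df.index.name = "event_id"
    df["mean_change"] = df[columns].mean(axis=1)
    return df


def rank_events(
    comparison: pd.DataFrame,
    catalog: EventCatalog | None = None,
) -> pd.DataFrame:
    """Rank events by mean improvement, descending (1 = largest).

    Dense ranking; exact ties are broken by catalog index when a catalog is
    given, else by event_id.  Returns a DataFrame sorted by rank with
    columns ``mean_change`` and ``rank``.
    """
    if comparison.empty:
        raise PanelError("empty span comparison")
    means = comparison["mean_change"]

    def tiebreak(event_id: str):
        if catalog is not None and event_id in catalog:
            return (0, catalog.index_of(event_id))
        return (1, event_id)

    order = sorted(means.index, key=lambda e: (-means[e], tiebreak(e)))
    # dense ranks: equal means share a rank
    ranks: dict[str, int] = {}
    rank = 0
    prev = None
    for event_id in order:
        if prev is None or means[event_id] != prev:
            rank += 1
            prev = means[event_id]
        ranks[event_id] = rank
    out = pd.DataFrame(
        {"mean_change": [means[e] for e in order], "rank": [ranks[e] for e in order]},
        index=pd.Index(order, name="event_id"),
    )
    return out
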