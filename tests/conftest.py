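"""Shared fixtures: small hand-built archives, windows and lexica."""

from datetime import date, datetime, time, timedelta, timezone

import pytest

from searchtrace.archive_io import SearchArchive, SearchQuery
from searchtrace.synthetic import fixture_lexicon
from searchtrace.windowing import WINDOW_DAYS, ObservationWindow

UTC = timezone.utc
WINDOW_START = datetime(2018, 3, 1, tzinfo=UTC)


def sq(ts: datetime, text: str = "hello world", source: str = "search") -> SearchQuery:
    return SearchQuery(ts, text, source)


def make_window(
    queries,
    start: datetime = WINDOW_START,
    task: str = "diagnostic",
    label: str = "SSD",
    lookback=(),
) -> ObservationWindow:
    end = start + timedelta(days=WINDOW_DAYS)
    return ObservationWindow(
        "p1", task, label, end, start, end, list(queries), lookback_queries=list(lookback)
    )


def daily_archive(
    pid: str, first: date, last: date, hour: int = 12, text: str = "hello world"
) -> SearchArchive:
    """One query per day at a fixed hour, inclusive of both end dates."""
    queries = [
        sq(datetime.combine(first + timedelta(days=i), time(hour), tzinfo=UTC), text)
        for i in range((last - first).days + 1)
    ]
    return SearchArchive(pid, queries)


@pytest.fixture(scope="session")
def lex51():
    return fixture_lexicon()


@pytest.fixture()
def toy_dic(tmp_path):
    path = tmp_path / "toy.dic"
    path.write_text(
        "%\n"
        "1\talpha\n"
        "2\tbeta\n"
        "3\tgamma\n"
        "%\n"
        "sleep\t1\n"
        "anger\t2\n"
        "mad\t2\n"
        "happ*\t1\t3\n"
        "happily\t3\n",
        encoding="utf-8",
    )
    return path
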