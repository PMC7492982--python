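"""Read and write personal search-history archives and clinical timelines.

The archive format of record is the Google Takeout "My Activity" JSON export
(an array of records whose ``title`` is "Searched for <text>" or
"Visited <url>" and whose ``time`` is an ISO-8601 timestamp).  Parsed
archives are held as :class:`SearchArchive` objects and can be round-tripped
through a canonical JSONL store (one query per line, UTF-8, fields
``timestamp``/``text``/``source``).

Clinical context arrives as a CSV of per-participant group labels and
hospitalization intervals, one row per hospitalization (rows optional for
healthy volunteers), loaded into :class:`ClinicalTimeline` objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SOURCES = ("search", "browse")
GROUPS = ("SSD", "HV")

_SEARCH_PREFIX = "Searched for "
_VISIT_PREFIX = "Visited "


class ArchiveError(ValueError):
    """Malformed or unusable search archive input."""


class EmptyArchiveError(ArchiveError):
    """An archive file parsed successfully but yielded zero usable queries."""


class TimelineError(ValueError):
    """Clinical timeline CSV violates an invariant."""


@dataclass(frozen=True)
class SearchQuery:
    """One time-stamped query.  ``timestamp`` must be timezone-aware."""

    timestamp: datetime
    text: str
    source: str = "search"

    def __post_init__(self) -> None:
        if self.timestamp.tzinfo is None:
            raise ArchiveError(f"naive timestamp for query {self.text!r}")
        if not self.text.strip():
            raise ArchiveError("query text empty after trimming")
        if self.source not in SOURCES:
            raise ArchiveError(f"unknown source {self.source!r}")


@dataclass
class ParseReport:
    """Bookkeeping for records dropped during Takeout parsing."""

    n_records: int = 0
    n_usable: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.drop_reasons.values())

    def drop(self, reason: str) -> None:
        self.drop_reasons[reason] = self.drop_reasons.get(reason, 0) + 1


@dataclass
class SearchArchive:
    """All queries of one participant, sorted ascending by timestamp."""

    participant_id: str
    queries: list[SearchQuery]
    report: ParseReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise ArchiveError("participant_id must be non-empty")
        self.queries = sorted(self.queries, key=lambda q: q.timestamp)

    def __len__(self) -> int:
        return len(self.queries)

    @property
    def first_time(self) -> datetime | None:
        return self.queries[0].timestamp if self.queries else None

    @property
    def last_time(self) -> datetime | None:
        return self.queries[-1].timestamp if self.queries else None

    def filtered(self, sources: Sequence[str] = ("search",)) -> "SearchArchive":
        """Archive restricted to the given sources (default: search only)."""
        return SearchArchive(
            self.participant_id,
            [q for q in self.queries if q.source in sources],
        )


@dataclass
class ClinicalTimeline:
    """Group label plus ordered, non-overlapping hospitalization intervals."""

    participant_id: str
    group: str
    hospitalizations: list[tuple[date, date]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise TimelineError(
                f"participant {self.participant_id}: unknown group {self.group!r}"
            )
        if self.group == "HV" and self.hospitalizations:
            raise TimelineError(
                f"participant {self.participant_id}: HV timeline must have no hospitalizations"
            )
        self.hospitalizations = sorted(self.hospitalizations)
        prev_discharge: date | None = None
        for adm, dis in self.hospitalizations:
            if dis < adm:
                raise TimelineError(
                    f"participant {self.participant_id}: discharge {dis} before admission {adm}"
                )
            if prev_discharge is not None and adm <= prev_discharge:
                raise TimelineError(
                    f"participant {self.participant_id}: overlapping hospitalizations at {adm}"
                )
            prev_discharge = dis


def _parse_time(value: str) -> datetime:
    ts = datetime.fromisoformat(value.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        raise ValueError("naive timestamp")
    return ts


def _apply_tz_policy(ts: datetime, policy: str) -> datetime:
    if policy == "export":
        return ts
    if policy.upper() == "UTC":
        return ts.astimezone(timezone.utc)
    # fixed numeric offset such as "-05:00" or "+01:30"
    sign = -1 if policy.startswith("-") else 1
    hh, _, mm = policy.lstrip("+-").partition(":")
    off = timezone(sign * timedelta(hours=int(hh), minutes=int(mm or 0)))
    return ts.astimezone(off)


def parse_takeout(
    path: str | Path,
    timezone_policy: str = "export",
    participant_id: str | None = None,
) -> SearchArchive:
    """Parse a Takeout "My Activity" JSON export into a :class:`SearchArchive`.

    ``timezone_policy`` is ``"export"`` (keep each record's own UTC offset),
    ``"UTC"``, or a fixed offset string like ``"-05:00"``; circadian features
    downstream bin by the stored offset, so choose the participant's local
    zone here.  Records without a parseable time, with an unrecognized title,
    or with empty residual text are dropped and counted in ``archive.report``.

    Raises :class:`ArchiveError` (naming the byte offset) on malformed JSON
    and :class:`EmptyArchiveError` when no usable record remains.
    """
    path = Path(path)
    pid = participant_id or path.stem
    try:
        records = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ArchiveError(
            f"{path}: malformed JSON at byte offset {exc.pos}: {exc.msg}"
        ) from exc
    if not isinstance(records, list):
        raise ArchiveError(f"{path}: expected a JSON array of activity records")

    report = ParseReport(n_records=len(records))
    queries: list[SearchQuery] = []
    for rec in records:
        title = rec.get("title", "") if isinstance(rec, dict) else ""
        if title.startswith(_SEARCH_PREFIX):
            source, text = "search", title[len(_SEARCH_PREFIX):]
        elif title.startswith(_VISIT_PREFIX):
            source, text = "browse", title[len(_VISIT_PREFIX):]
        else:
            report.drop("unrecognized_title")
            continue
        try:
            ts = _apply_tz_policy(_parse_time(rec["time"]), timezone_policy)
        except (KeyError, ValueError, TypeError):
            report.drop("unparseable_time")
            continue
        text = text.strip()
        if not text:
            report.drop("empty_text")
            continue
        queries.append(SearchQuery(ts, text, source))
    report.n_usable = len(queries)
    if not queries:
        raise EmptyArchiveError(f"{path}: no usable records (of {len(records)})")
    return SearchArchive(pid, queries, report=report)


def write_takeout(archive: SearchArchive, path: str | Path) -> None:
    """Emit an archive back into the Takeout JSON dialect (for round-trip tests)."""
    prefix = {"search": _SEARCH_PREFIX, "browse": _VISIT_PREFIX}
    records = [
        {
            "header": "Search",
            "title": prefix[q.source] + q.text,
            "time": q.timestamp.isoformat(),
        }
        for q in archive.queries
    ]
    Path(path).write_text(
        json.dumps(records, ensure_ascii=False, indent=1), encoding="utf-8"
    )


def write_canonical(archive: SearchArchive, path: str | Path) -> None:
    """Write the canonical JSONL store: one query per line, UTF-8."""
    with open(path, "w", encoding="utf-8") as fh:
        for q in archive.queries:
            fh.write(
                json.dumps(
                    {
                        "timestamp": q.timestamp.isoformat(),
                        "text": q.text,
                        "source": q.source,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_canonical(path: str | Path, participant_id: str | None = None) -> SearchArchive:
    """Read a canonical JSONL archive; inverse of :func:`write_canonical`."""
    path = Path(path)
    pid = participant_id or path.stem
    queries = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                queries.append(
                    SearchQuery(_parse_time(rec["timestamp"]), rec["text"], rec["source"])
                )
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise ArchiveError(f"{path}:{i}: bad canonical record: {exc}") from exc
    return SearchArchive(pid, queries)


def read_timeline(path: str | Path) -> list[ClinicalTimeline]:
    """Load clinical timelines from CSV.

    Expected columns: ``participant_id, group, admission, discharge`` with
    ISO-8601 dates; admission/discharge may be empty for HV rows.  One
    :class:`ClinicalTimeline` per participant is returned in file order;
    overlapping intervals or discharge < admission raise
    :class:`TimelineError` naming the participant.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"participant_id", "group", "admission", "discharge"}
    missing = required - set(df.columns)
    if missing:
        raise TimelineError(f"{path}: missing columns {sorted(missing)}")
    timelines: list[ClinicalTimeline] = []
    for pid in df["participant_id"].drop_duplicates():
        rows = df[df["participant_id"] == pid]
        groups = rows["group"].unique()
        if len(groups) != 1:
            raise TimelineError(f"participant {pid}: conflicting group labels")
        hosps = []
        for _, row in rows.iterrows():
            if not row["admission"] and not row["discharge"]:
                continue
            try:
                adm = date.fromisoformat(row["admission"])
                dis = date.fromisoformat(row["discharge"])
            except ValueError as exc:
                raise TimelineError(f"participant {pid}: bad date ({exc})") from exc
            hosps.append((adm, dis))
        timelines.append(ClinicalTimeline(pid, groups[0], hosps))
    return timelines


def write_timeline(timelines: Iterable[ClinicalTimeline], path: str | Path) -> None:
    """Write timelines to the CSV format read by :func:`read_timeline`."""
    rows = []
    for tl in timelines:
        if tl.hospitalizations:
            for adm, dis in tl.hospitalizations:
                rows.append((tl.participant_id, tl.group, adm.isoformat(), dis.isoformat()))
        else:
            rows.append((tl.participant_id, tl.group, "", ""))
    pd.DataFrame(
        rows, columns=["participant_id", "group", "admission", "discharge"]
    ).to_csv(path, index=False)
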