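"""Segment archives into labeled 4-week observation windows.

Three window constructors mirror the two analysis tasks:

* :func:`diagnostic_window` — the 28 days immediately preceding the first
  psychiatric hospitalization of an SSD participant.
* :func:`control_window` — a seeded, randomly placed 28-day window inside a
  healthy volunteer's archive (redrawn, bounded, until it contains a query).
* :func:`relapse_windows` — alternating "illness" (28 days before each
  relapse admission) and "health" (28 days after each discharge) windows,
  subject to the between-hospitalization gap rules.

All windows are half-open ``[start, end)`` and exactly 28 days long; the
admission instant belongs to the hospitalization, not the pre-window.  Each
window also carries the queries of the 4 calendar days preceding its start
(``lookback_queries``) so the 8-bin 4-day histograms can span a full 32-day
lookback from the window end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, tzinfo
from typing import Sequence

import numpy as np
import pandas as pd

from .archive_io import ClinicalTimeline, SearchArchive, SearchQuery

WINDOW_DAYS = 28
LOOKBACK_DAYS = 32
TASKS = ("diagnostic", "relapse")
_WINDOW = timedelta(days=WINDOW_DAYS)


class WindowingError(ValueError):
    """A window constructor was used against its preconditions."""


@dataclass(frozen=True)
class ExclusionNotice:
    """Why a participant (or one candidate window) contributes no window."""

    participant_id: str
    task: str
    reason: str


@dataclass
class ObservationWindow:
    """A labeled 28-day slice of one participant's queries.

    ``anchor`` is the clinical date the window is defined against (admission
    for diagnostic/illness windows, discharge for health windows, the drawn
    start date for controls).  ``lookback_queries`` hold days 28–31 prior to
    ``end`` and are used only by the 4-day histograms.
    """

    participant_id: str
    task: str
    label: str
    anchor: datetime
    start: datetime
    end: datetime
    queries: list[SearchQuery]
    lookback_queries: list[SearchQuery] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise WindowingError(f"unknown task {self.task!r}")
        if self.end - self.start != _WINDOW:
            raise WindowingError(
                f"window must span exactly {WINDOW_DAYS} days, got {self.end - self.start}"
            )
        self.queries = sorted(self.queries, key=lambda q: q.timestamp)
        for q in self.queries:
            if not (self.start <= q.timestamp < self.end):
                raise WindowingError(
                    f"query at {q.timestamp} outside window [{self.start}, {self.end})"
                )

    @property
    def n_queries(self) -> int:
        return len(self.queries)


def _tz_of(archive: SearchArchive) -> tzinfo:
    if not archive.queries:
        raise WindowingError(f"archive {archive.participant_id} is empty")
    return archive.queries[0].timestamp.tzinfo


def _midnight(d: date, tz: tzinfo) -> datetime:
    return datetime.combine(d, time.min, tzinfo=tz)


def _slice(archive: SearchArchive, start: datetime, end: datetime) -> list[SearchQuery]:
    return [q for q in archive.queries if start <= q.timestamp < end]


def _build(
    archive: SearchArchive,
    pid: str,
    task: str,
    label: str,
    anchor: datetime,
    start: datetime,
    floor: datetime | None = None,
) -> ObservationWindow:
    end = start + _WINDOW
    lb_start = end - timedelta(days=LOOKBACK_DAYS)
    if floor is not None and lb_start < floor:
        lb_start = floor
    return ObservationWindow(
        pid,
        task,
        label,
        anchor,
        start,
        end,
        _slice(archive, start, end),
        lookback_queries=_slice(archive, lb_start, start),
    )


def diagnostic_window(
    archive: SearchArchive, timeline: ClinicalTimeline
) -> ObservationWindow | ExclusionNotice:
    """The 28 days immediately before the first admission of an SSD participant.

    Returns an :class:`ExclusionNotice` when no query falls inside the window
    (such participants are excluded from the diagnostic analysis).
    """
    if timeline.group != "SSD" or not timeline.hospitalizations:
        raise WindowingError(
            f"diagnostic window requires an SSD timeline with >=1 hospitalization "
            f"(participant {timeline.participant_id})"
        )
    if not archive.queries:
        return ExclusionNotice(archive.participant_id, "diagnostic", "empty archive")
    tz = _tz_of(archive)
    end = _midnight(timeline.hospitalizations[0][0], tz)
    win = _build(archive, archive.participant_id, "diagnostic", "SSD", end, end - _WINDOW)
    if not win.queries:
        return ExclusionNotice(
            archive.participant_id,
            "diagnostic",
            "no search data in the 4 weeks before the first hospitalization",
        )
    return win


def control_window(
    archive: SearchArchive, rng_seed: int, max_retries: int = 100
) -> ObservationWindow | ExclusionNotice:
    """A randomly placed 28-day control window for a healthy volunteer.

    The start day is drawn uniformly from the archive's calendar span
    (the window must fit before the last query) and redrawn up to
    ``max_retries`` times until at least one query falls inside.
    Deterministic for a fixed ``rng_seed``.
    """
    if not archive.queries:
        return ExclusionNotice(archive.participant_id, "diagnostic", "empty archive")
    tz = _tz_of(archive)
    day0 = _midnight(archive.first_time.date(), tz)
    span_days = (archive.last_time - day0).days + 1
    n_candidates = span_days - WINDOW_DAYS + 1
    if n_candidates <= 0:
        return ExclusionNotice(
            archive.participant_id, "diagnostic", "archive span shorter than 28 days"
        )
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_retries):
        k = int(rng.integers(0, n_candidates))
        start = day0 + timedelta(days=k)
        win = _build(archive, archive.participant_id, "diagnostic", "HV", start, start)
        if win.queries:
            return win
    return ExclusionNotice(
        archive.participant_id,
        "diagnostic",
        f"no nonempty 28-day window found in {max_retries} draws",
    )


def relapse_windows(
    archive: SearchArchive,
    timeline: ClinicalTimeline,
    month_days: int = WINDOW_DAYS,
) -> tuple[list[ObservationWindow], list[ExclusionNotice]]:
    """Illness and health windows around relapse hospitalizations.

    For hospitalizations ``h_1..h_n`` sorted by admission:

    * illness windows: the 28 days before ``admission_i`` for ``i >= 2``,
      skipped when the gap from the previous discharge is under
      ``month_days`` (too little data to reflect a distinct illness period);
    * health windows: the 28 days after ``discharge_i``, emitted for
      non-final hospitalizations only when the gap to the next admission is
      at least ``2 * month_days``, and for the final hospitalization whenever
      the archive extends at least 28 days past discharge.

    No window contains data prior to the first admission.  Windows with zero
    queries are dropped with a notice.
    """
    if timeline.group != "SSD":
        raise WindowingError(
            f"relapse windows require an SSD timeline (participant {timeline.participant_id})"
        )
    pid = timeline.participant_id
    if not archive.queries:
        return [], [ExclusionNotice(pid, "relapse", "empty archive")]
    tz = _tz_of(archive)
    hosps = [(_midnight(a, tz), _midnight(d, tz)) for a, d in timeline.hospitalizations]
    if not hosps:
        return [], [ExclusionNotice(pid, "relapse", "no hospitalizations")]
    first_admission = hosps[0][0]
    month = timedelta(days=month_days)

    windows: list[ObservationWindow] = []
    notices: list[ExclusionNotice] = []

    def emit(label: str, anchor: datetime, start: datetime) -> None:
        win = _build(archive, pid, "relapse", label, anchor, start, floor=first_admission)
        if win.start < first_admission:
            raise WindowingError(
                f"participant {pid}: relapse window would precede the first admission"
            )
        if win.queries:
            windows.append(win)
        else:
            notices.append(
                ExclusionNotice(pid, "relapse", f"no queries in {label} window at {anchor.date()}")
            )

    for i, (adm, dis) in enumerate(hosps):
        if i >= 1:  # illness window before each relapse (2nd and later) admission
            prev_discharge = hosps[i - 1][1]
            if adm - prev_discharge >= month:
                emit("illness", adm, adm - _WINDOW)
            else:
                notices.append(
                    ExclusionNotice(
                        pid,
                        "relapse",
                        f"illness window before {adm.date()} skipped: "
                        f"under {month_days} days since previous discharge",
                    )
                )
        is_final = i == len(hosps) - 1
        if is_final:
            if archive.last_time >= dis + _WINDOW:
                emit("health", dis, dis)
            else:
                notices.append(
                    ExclusionNotice(
                        pid,
                        "relapse",
                        f"health window after final discharge {dis.date()} skipped: "
                        "under 28 days of archive remain",
                    )
                )
        else:
            next_admission = hosps[i + 1][0]
            if next_admission - dis >= 2 * month:
                emit("health", dis, dis)
            else:
                notices.append(
                    ExclusionNotice(
                        pid,
                        "relapse",
                        f"health window after {dis.date()} skipped: "
                        f"under {2 * month_days} days before next admission",
                    )
                )
    return windows, notices


def window_manifest(
    windows: Sequence[ObservationWindow | ExclusionNotice],
) -> pd.DataFrame:
    """Tabulate windows (and exclusions) for exchange with the feature stage."""
    rows = []
    for w in windows:
        if isinstance(w, ExclusionNotice):
            rows.append(
                {
                    "participant_id": w.participant_id,
                    "task": w.task,
                    "label": "excluded",
                    "anchor": "",
                    "start": "",
                    "end": "",
                    "n_queries": 0,
                    "note": w.reason,
                }
            )
        else:
            rows.append(
                {
                    "participant_id": w.participant_id,
                    "task": w.task,
                    "label": w.label,
                    "anchor": w.anchor.isoformat(),
                    "start": w.start.isoformat(),
                    "end": w.end.isoformat(),
                    "n_queries": w.n_queries,
                    "note": "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "task",
            "label",
            "anchor",
            "start",
            "end",
            "n_queries",
            "note",
        ],
    )
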