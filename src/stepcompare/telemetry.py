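"""Per-session platform telemetry and derived session measures.

A session is one daily visit: the participant rates their exercise motivation
(1-5), peeks at zero or more candidate profiles, commits to one profile to
view in full, dwells on its Details page, and rates motivation again.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .designs import TargetProfile, direction_of
from .errors import ConsistencyError, InvalidRatingError

__all__ = [
    "SessionLog",
    "SessionMetrics",
    "motivation_change",
    "derive_session_metrics",
    "write_session_jsonl",
    "read_session_jsonl",
]

RATING_MIN, RATING_MAX = 1, 5


def _check_rating(value: int, name: str) -> int:
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise InvalidRatingError(f"{name} must be an integer 1-5, got {value!r}")
    if not (RATING_MIN <= value <= RATING_MAX):
        raise InvalidRatingError(f"{name} must lie in 1-5, got {value}")
    return value


def motivation_change(m_pre: int, m_post: int) -> int:
    """Change in motivation: the post-exposure rating minus the pre rating."""
    _check_rating(m_pre, "m_pre")
    _check_rating(m_post, "m_post")
    return m_post - m_pre


@dataclass(frozen=True)
class SessionLog:
    """One platform session's raw telemetry."""

    participant_id: str
    day_index: int
    login_time: str  # ISO timestamp
    m_pre: int
    peek_events: tuple[tuple[str, str], ...]  # (username, ISO timestamp)
    final_selection: str
    elements_viewed: int
    viewing_seconds: float
    m_post: int

    def __post_init__(self):
        _check_rating(self.m_pre, "m_pre")
        _check_rating(self.m_post, "m_post")
        if self.viewing_seconds < 0:
            raise ConsistencyError("viewing_seconds must be >= 0")
        if self.elements_viewed < 0:
            raise ConsistencyError("elements_viewed must be >= 0")

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "day_index": self.day_index,
            "login_time": self.login_time,
            "m_pre": self.m_pre,
            "peek_events": [list(p) for p in self.peek_events],
            "final_selection": self.final_selection,
            "elements_viewed": self.elements_viewed,
            "viewing_seconds": self.viewing_seconds,
            "m_post": self.m_post,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SessionLog":
        return cls(
            participant_id=d["participant_id"],
            day_index=int(d["day_index"]),
            login_time=d["login_time"],
            m_pre=int(d["m_pre"]),
            peek_events=tuple((str(u), str(t)) for u, t in d.get("peek_events", ())),
            final_selection=d["final_selection"],
            elements_viewed=int(d["elements_viewed"]),
            viewing_seconds=float(d["viewing_seconds"]),
            m_post=int(d["m_post"]),
        )


@dataclass(frozen=True)
class SessionMetrics:
    """Derived per-session measures used by the analysis layer."""

    first_equals_final: bool
    viewing_seconds: float
    elements_viewed: int
    motivation_change: int
    selected_direction: str
    selected_scale_category: str
    selected_username: str
    selected_steps: int
    fabricated_selected: bool


def derive_session_metrics(
    log: SessionLog,
    offered: Sequence[TargetProfile],
    prev_day_steps: int,
) -> SessionMetrics:
    """Derive session measures from raw telemetry and the day's offer set.

    ``first_equals_final`` is true when the first peeked profile is the one
    ultimately committed to (vacuously true when the participant committed
    without peeking around first).  Direction and scale category come from the
    selected profile's displayed total against the participant's own
    previous-day steps.
    """
    from .prep import code_scale_category  # deferred: avoids import cycle

    by_name = {p.username: p for p in offered}
    if log.final_selection not in by_name:
        raise ConsistencyError(
            f"final selection {log.final_selection!r} is not among the "
            f"offered usernames {sorted(by_name)}"
        )
    selected = by_name[log.final_selection]
    first_equals_final = (
        not log.peek_events or log.peek_events[0][0] == log.final_selection
    )
    return SessionMetrics(
        first_equals_final=first_equals_final,
        viewing_seconds=log.viewing_seconds,
        elements_viewed=log.elements_viewed,
        motivation_change=motivation_change(log.m_pre, log.m_post),
        selected_direction=direction_of(selected.displayed_steps, prev_day_steps),
        selected_scale_category=code_scale_category(
            selected.displayed_steps, prev_day_steps
        ),
        selected_username=selected.username,
        selected_steps=selected.displayed_steps,
        fabricated_selected=selected.fabricated,
    )


def count_elements_viewed(
    click_events: Sequence[str], distinct: bool = True
) -> int:
    """Number of profile detail fields viewed from raw click events.

    By default repeat clicks on the same field do not re-count (the platform
    measures how many fields a user opened, not their clicking tempo);
    ``distinct=False`` counts every click.
    """
    return len(set(click_events)) if distinct else len(click_events)


def write_session_jsonl(
    path: str | Path,
    records: Iterable[Mapping],
) -> None:
    """Write session records (SessionLog dicts plus any context keys) as JSONL."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_session_jsonl(path: str | Path) -> list[dict]:
    """Read JSONL session records back into dicts."""
    path = Path(path)
    out = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out
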