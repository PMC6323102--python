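"""Multistate event-history records and their counting-process summaries.

A subject's observed history is a sequence of sojourns.  Each sojourn is
one :class:`EventRecord`: the subject entered ``from_state`` at
``entry_time`` and left it at ``exit_time``, either through a transition
into ``to_state`` or through right-censoring (``to_state`` equal to the
:data:`CENSORED` sentinel).  Left-truncation is encoded by a positive
``entry_time`` of the first sojourn.

For one transition of interest, :func:`build_counting_data` aggregates a
record collection into the jump times of the transition-specific
counting process N, the jump sizes ΔN, and the at-risk counts Y just
prior to each jump — everything the Nelson–Aalen estimator and its wild
bootstrap need.

At-risk convention: a subject occupying ``from_state`` on the sojourn
(entry, exit] is at risk at time s iff entry < s ≤ exit, so Y(s) is the
count "just prior to" s.  When an event and a censoring share the same
time, the censored subject is still counted at risk for that event
(events precede censorings); pass ``censoring_precedes_events=True`` to
flip the convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "CENSORED",
    "TransitionKey",
    "EventRecord",
    "CountingData",
    "HistoryReport",
    "build_counting_data",
    "validate_histories",
    "records_to_frame",
    "as_frame",
    "read_event_history",
    "write_event_history",
]

#: Sentinel label marking a right-censored sojourn exit.
CENSORED = "cens"

COLUMNS = ["id", "entry", "exit", "from", "to"]


@dataclass(frozen=True)
class TransitionKey:
    """An ordered pair of distinct state labels, e.g. 0 → 2."""

    from_state: str
    to_state: str

    def __post_init__(self):
        object.__setattr__(self, "from_state", str(self.from_state))
        object.__setattr__(self, "to_state", str(self.to_state))
        if self.from_state == self.to_state:
            raise ValueError("a transition must change the state")

    def __str__(self) -> str:
        return f"{self.from_state}->{self.to_state}"


@dataclass(frozen=True)
class EventRecord:
    """One observed sojourn of one subject."""

    subject_id: str
    entry_time: float
    exit_time: float
    from_state: str
    to_state: str  # state label, or CENSORED

    def __post_init__(self):
        if not self.entry_time < self.exit_time:
            raise ValueError(
                f"record {self.subject_id!r}: entry_time must be < exit_time "
                f"({self.entry_time} vs {self.exit_time})"
            )
        if str(self.to_state) == str(self.from_state):
            raise ValueError(
                f"record {self.subject_id!r}: exit into the occupied state"
            )


@dataclass(frozen=True)
class CountingData:
    """Per-transition jump grid of (N, Y) for a record collection.

    ``jump_times`` are the distinct event times in (0, tau], ``delta_n``
    the (positive integer) jump sizes of N, and ``y_at_jumps`` the
    at-risk counts just prior to each jump.  ``n`` is the sample-size
    related normalizer (number of subjects by default) and ``tau`` the
    observation horizon.
    """

    transition: TransitionKey
    jump_times: np.ndarray
    delta_n: np.ndarray
    y_at_jumps: np.ndarray
    n: int
    tau: float

    def __post_init__(self):
        t = np.asarray(self.jump_times, dtype=float)
        d = np.asarray(self.delta_n, dtype=np.int64)
        y = np.asarray(self.y_at_jumps, dtype=np.int64)
        if not (t.shape == d.shape == y.shape):
            raise ValueError("jump_times, delta_n and y_at_jumps must align")
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValueError("jump_times must be strictly increasing")
            if t[0] <= 0 or t[-1] > self.tau:
                raise ValueError("jump times must lie in (0, tau]")
            if np.any(d < 1):
                raise ValueError("delta_n must be positive")
            if np.any(d > y):
                raise ValueError("delta_n cannot exceed the at-risk count")
        if self.n < 1 or self.tau <= 0:
            raise ValueError("n must be >= 1 and tau > 0")
        object.__setattr__(self, "jump_times", t)
        object.__setattr__(self, "delta_n", d)
        object.__setattr__(self, "y_at_jumps", y)

    @property
    def num_jumps(self) -> int:
        return int(self.jump_times.size)

    @property
    def num_events(self) -> int:
        return int(self.delta_n.sum())


Records = Union[pd.DataFrame, Iterable[EventRecord]]


def records_to_frame(records: Iterable[EventRecord]) -> pd.DataFrame:
    rows = [
        (r.subject_id, r.entry_time, r.exit_time, str(r.from_state), str(r.to_state))
        for r in records
    ]
    return pd.DataFrame(rows, columns=COLUMNS)


def as_frame(records: Records) -> pd.DataFrame:
    """Normalize a record collection to the canonical DataFrame layout."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"event-history frame misses columns {missing}")
        frame = records.loc[:, COLUMNS].copy()
    else:
        frame = records_to_frame(records)
    frame["entry"] = frame["entry"].astype(float)
    frame["exit"] = frame["exit"].astype(float)
    frame["from"] = frame["from"].astype(str)
    frame["to"] = frame["to"].astype(str)
    bad = frame["entry"] >= frame["exit"]
    if bad.any():
        first = frame.index[bad][0]
        raise ValueError(
            f"record at row {first}: entry_time must be < exit_time"
        )
    return frame


def _check_states(frame: pd.DataFrame, state_space: Sequence[str] | None) -> None:
    if state_space is None:
        return
    allowed = {str(s) for s in state_space}
    seen = set(frame["from"]).union(frame["to"]) - {CENSORED}
    unknown = seen - allowed
    if unknown:
        raise ValueError(f"unknown state labels {sorted(unknown)} vs declared state space")


def build_counting_data(
    records: Records,
    transition: TransitionKey,
    tau: float,
    n: int | None = None,
    *,
    state_space: Sequence[str] | None = None,
    censoring_precedes_events: bool = False,
) -> CountingData:
    """Aggregate event-history records into per-transition counting data.

    Y at a jump time s counts records with the matching ``from`` state and
    entry < s ≤ exit; ΔN at s counts matching transition records with
    exit == s.  Event times beyond ``tau`` are dropped (the subjects still
    contribute to Y before tau).
    """
    frame = as_frame(records)
    _check_states(frame, state_space)
    if n is None:
        n = frame["id"].nunique()
    if tau <= 0:
        raise ValueError("tau must be positive")

    occ = frame[frame["from"] == transition.from_state]
    ev = occ[(occ["to"] == transition.to_state) & (occ["exit"] <= tau)]

    jump_times, delta_n = np.unique(ev["exit"].to_numpy(), return_counts=True)

    entries = np.sort(occ["entry"].to_numpy())
    if censoring_precedes_events:
        exits_event = np.sort(occ.loc[occ["to"] != CENSORED, "exit"].to_numpy())
        exits_cens = np.sort(occ.loc[occ["to"] == CENSORED, "exit"].to_numpy())
        gone = np.searchsorted(exits_event, jump_times, side="left") + np.searchsorted(
            exits_cens, jump_times, side="right"
        )
    else:
        exits = np.sort(occ["exit"].to_numpy())
        gone = np.searchsorted(exits, jump_times, side="left")
    y = np.searchsorted(entries, jump_times, side="left") - gone

    return CountingData(
        transition=transition,
        jump_times=jump_times,
        delta_n=delta_n,
        y_at_jumps=y,
        n=int(n),
        tau=float(tau),
    )


@dataclass
class HistoryReport:
    """Diagnostics from :func:`validate_histories` (reporting only)."""

    overlaps: list
    zero_length: list
    self_transitions: list
    unknown_states: list

    @property
    def ok(self) -> bool:
        return not (
            self.overlaps or self.zero_length or self.self_transitions or self.unknown_states
        )

    def __str__(self) -> str:
        if self.ok:
            return "event histories OK"
        parts = []
        for name in ("overlaps", "zero_length", "self_transitions", "unknown_states"):
            items = getattr(self, name)
            if items:
                parts.append(f"{name}: {items}")
        return "; ".join(parts)


def validate_histories(
    records: Records, state_space: Sequence[str] | None = None
) -> HistoryReport:
    """List overlapping sojourns, zero-length sojourns, exits into the
    occupied state, and labels outside the declared state space.  Never
    raises on, nor mutates, the input."""
    if isinstance(records, pd.DataFrame):
        rows = [
            (r["id"], float(r["entry"]), float(r["exit"]), str(r["from"]), str(r["to"]))
            for _, r in records.iterrows()
        ]
    else:
        rows = [_as_row(r) for r in records]

    zero_length = [(sid, entry) for sid, entry, exit_, _, _ in rows if entry >= exit_]
    self_transitions = [
        (sid, exit_) for sid, _, exit_, src, dst in rows if src == dst
    ]
    overlaps = []
    by_subject: dict = {}
    for sid, entry, exit_, _, _ in rows:
        by_subject.setdefault(sid, []).append((entry, exit_))
    for sid, ivs in by_subject.items():
        ivs.sort()
        for k in range(1, len(ivs)):
            if ivs[k][0] < ivs[k - 1][1]:
                overlaps.append((sid, ivs[k][0]))
    unknown = []
    if state_space is not None:
        allowed = {str(s) for s in state_space}
        seen = {src for *_, src, _ in rows} | {dst for *_, dst in rows}
        unknown = sorted(seen - allowed - {CENSORED})
    return HistoryReport(overlaps, zero_length, self_transitions, unknown)


def _as_row(r):
    # Reporting must not raise on invalid data, so plain 5-tuples are
    # accepted next to validated EventRecords.
    if isinstance(r, EventRecord):
        return (r.subject_id, r.entry_time, r.exit_time, str(r.from_state), str(r.to_state))
    sid, entry, exit_, src, dst = r
    return (sid, float(entry), float(exit_), str(src), str(dst))


def read_event_history(path, *, sep: str = ",") -> pd.DataFrame:
    """Read the event-history file: header ``id,entry,exit,from,to``,
    value ``cens`` in ``to`` marking censoring."""
    frame = pd.read_csv(path, sep=sep, dtype={"id": str, "from": str, "to": str})
    return as_frame(frame)


def write_event_history(frame_or_records: Records, path, *, sep: str = ",") -> None:
    as_frame(frame_or_records).to_csv(path, sep=sep, index=False)
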