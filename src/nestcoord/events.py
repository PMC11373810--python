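"""Event-log I/O and derivation of activity bouts from raw annotation events.

The raw material of the analysis is a per-session event log: one row per
observed event (a bird appearing on / vanishing from the camera frame, or
entering / exiting the nest), annotated with a food-load flag on
reappearance.  :func:`derive_bouts` turns one bird's event stream into a
sequence of NEST / COLONY / FORAGING bouts tiling the whole session:

* time between ``nest_enter`` and ``nest_exit`` is NEST;
* an absence (``vanish`` .. ``appear``) shorter than the foraging gap
  (default 1 h) is bridged as COLONY;
* an absence of at least the gap is FORAGING during incubation; during
  chick rearing an absence ending with a food-load return is FORAGING (a
  provisioning trip) and a long absence without food is FORAGING flagged
  non-provisioning;
* all remaining observed time is COLONY.

Unobserved spans at the session edges are labeled by extrapolating the
adjacent state and the derivation reports that extrapolation occurred.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence, Union

import pandas as pd

from .core import (
    Bout,
    BoutSequence,
    Category,
    SessionRecord,
    Stage,
    ValidationError,
    _merge_adjacent,
)

#: Default absence threshold separating colony loitering from a foraging
#: trip: 1 hour, anchored to the species' short-trip durations (~2-2.4 h).
DEFAULT_FORAGING_GAP = 3600

EVENT_COLUMNS = [
    "session_id",
    "pair_id",
    "year",
    "stage",
    "phase",
    "individual_id",
    "sex",
    "t_seconds",
    "kind",
    "food_load",
]

BOUT_COLUMNS = ["session_id", "individual_id", "category", "start_s", "end_s", "food"]

META_COLUMNS = [
    "session_id",
    "pair_id",
    "year",
    "stage",
    "phase",
    "duration_s",
    "female_id",
    "male_id",
    "extrapolated_f",
    "extrapolated_m",
]


class EventKind(str, enum.Enum):
    APPEAR = "appear"
    VANISH = "vanish"
    NEST_ENTER = "nest_enter"
    NEST_EXIT = "nest_exit"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True, order=True)
class EventRecord:
    """One observed event for one individual, at 1-s precision."""

    t: int
    kind: EventKind = field(compare=False)
    individual_id: str = field(compare=False)
    sex: str = field(compare=False, default="F")
    food_load: bool = field(compare=False, default=False)


@dataclass
class SessionEvents:
    """All events of one recording session, grouped per individual."""

    session_id: str
    pair_id: str
    year: int
    stage: Stage
    phase: Union[int, float, str]
    duration: int
    events: dict  # individual_id -> list[EventRecord], time-sorted
    sex: dict  # individual_id -> "F" | "M"


class DeriveResult(NamedTuple):
    sequence: BoutSequence
    extrapolated: bool


def _parse_bool(raw: str, line_no: int, column: str) -> bool:
    v = raw.strip().lower()
    if v in ("true", "1", "yes", "t"):
        return True
    if v in ("false", "0", "no", "f", ""):
        return False
    raise ValidationError(f"line {line_no}: cannot parse {column}={raw!r} as boolean")


def read_event_log(path, session_duration: int = None) -> list[SessionEvents]:
    """Read an event-log CSV into per-session, per-individual event lists.

    Parameters
    ----------
    path : path-like
        CSV with header ``session_id,pair_id,year,stage,phase,individual_id,
        sex,t_seconds,kind,food_load`` (UTF-8).
    session_duration : int, optional
        Nominal session length in seconds; every timestamp must fall in
        ``[0, session_duration]``.  Defaults to 48 h.

    Raises
    ------
    ValidationError
        On a malformed row (named by line number) or an alternation
        violation (named by individual and timestamp).
    """
    from .core import SESSION_48H

    if session_duration is None:
        session_duration = SESSION_48H
    path = Path(path)
    sessions: dict[str, SessionEvents] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != EVENT_COLUMNS:
            raise ValidationError(
                f"{path}: header must be {','.join(EVENT_COLUMNS)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            n = reader.line_num
            try:
                t = int(row["t_seconds"])
                kind = EventKind(row["kind"].strip().lower())
                year = int(row["year"])
                stage = Stage(row["stage"].strip().upper())
            except (KeyError, TypeError, ValueError) as exc:
                raise ValidationError(f"line {n}: malformed row ({exc})") from None
            if not 0 <= t <= session_duration:
                raise ValidationError(
                    f"line {n}: t_seconds={t} outside [0, {session_duration}]"
                )
            sex = row["sex"].strip().upper()
            if sex not in ("F", "M"):
                raise ValidationError(f"line {n}: sex must be F or M, got {row['sex']!r}")
            food = _parse_bool(row["food_load"], n, "food_load")
            sid = row["session_id"].strip()
            sess = sessions.get(sid)
            if sess is None:
                sess = SessionEvents(
                    session_id=sid,
                    pair_id=row["pair_id"].strip(),
                    year=year,
                    stage=stage,
                    phase=row["phase"].strip(),
                    duration=session_duration,
                    events={},
                    sex={},
                )
                sessions[sid] = sess
            ind = row["individual_id"].strip()
            sess.sex.setdefault(ind, sex)
            sess.events.setdefault(ind, []).append(
                EventRecord(t=t, kind=kind, individual_id=ind, sex=sex, food_load=food)
            )
    for sess in sessions.values():
        for ind, evs in sess.events.items():
            evs.sort(key=lambda e: e.t)
            _validate_events(evs, ind)
    return list(sessions.values())


def write_event_log(sessions: Sequence[SessionEvents], path) -> None:
    """Write per-session events back to the event-log CSV dialect."""
    rows = []
    for s in sessions:
        for ind in sorted(s.events):
            for e in s.events[ind]:
                rows.append(
                    {
                        "session_id": s.session_id,
                        "pair_id": s.pair_id,
                        "year": s.year,
                        "stage": Stage(s.stage).value,
                        "phase": s.phase,
                        "individual_id": ind,
                        "sex": s.sex.get(ind, e.sex),
                        "t_seconds": e.t,
                        "kind": e.kind.value,
                        "food_load": str(e.food_load).lower(),
                    }
                )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def _validate_events(events: Sequence[EventRecord], individual: str) -> None:
    """Check strict time ordering and per-kind alternation for one bird."""
    last_t = -1
    last_presence = None  # APPEAR / VANISH
    last_nest = None  # NEST_ENTER / NEST_EXIT
    for e in events:
        if e.t <= last_t:
            raise ValidationError(
                f"individual {individual}: events not strictly time-ordered at t={e.t}"
            )
        last_t = e.t
        if e.kind in (EventKind.APPEAR, EventKind.VANISH):
            if e.kind == last_presence:
                raise ValidationError(
                    f"individual {individual}: consecutive {e.kind.value} at t={e.t}"
                )
            last_presence = e.kind
        else:
            if e.kind == last_nest:
                raise ValidationError(
                    f"individual {individual}: consecutive {e.kind.value} at t={e.t}"
                )
            last_nest = e.kind


def _absence_category(
    length: int, stage: Stage, food: Optional[bool], foraging_gap: int
) -> tuple[Category, Optional[bool]]:
    """Label one absence interval. Returns (category, food flag for the bout)."""
    if stage is Stage.CHICK_REARING:
        if food:
            return Category.FORAGING, True
        if length >= foraging_gap:
            return Category.FORAGING, False  # non-provisioning long absence
        return Category.COLONY, None
    if length >= foraging_gap:
        return Category.FORAGING, None
    return Category.COLONY, None


def derive_bouts(
    events: Sequence[EventRecord],
    stage: Stage,
    duration: int,
    foraging_gap: int = DEFAULT_FORAGING_GAP,
) -> DeriveResult:
    """Derive one bird's tiling bout sequence from its time-sorted events.

    Returns
    -------
    DeriveResult
        ``sequence`` tiles ``[0, duration)`` with adjacent equal categories
        merged; ``extrapolated`` is True when a leading span before the
        first event or a trailing absence truncated by the session end had
        to be labeled by extrapolation.
    """
    stage = Stage(stage)
    if not events:
        raise ValidationError("cannot derive bouts from an empty event list")
    events = sorted(events, key=lambda e: e.t)
    _validate_events(events, events[0].individual_id)
    if events[-1].t > duration:
        raise ValidationError(
            f"event at t={events[-1].t} beyond session duration {duration}"
        )

    segments: list[Bout] = []
    extrapolated = False

    # Leading span [0, first event): state inferred from the first event kind.
    first = events[0]
    if first.t > 0:
        if first.kind is EventKind.APPEAR:
            cat, food = _absence_category(first.t, stage, first.food_load, foraging_gap)
            segments.append(Bout(cat, 0, first.t, food))
            extrapolated = True
        elif first.kind is EventKind.NEST_EXIT:
            segments.append(Bout(Category.NEST, 0, first.t))
            extrapolated = True
        else:  # VANISH or NEST_ENTER: the bird was visible in the colony
            segments.append(Bout(Category.COLONY, 0, first.t))
            extrapolated = True

    # state after each event: "colony" | "nest" | "away"
    state = {
        EventKind.APPEAR: "colony",
        EventKind.VANISH: "away",
        EventKind.NEST_ENTER: "nest",
        EventKind.NEST_EXIT: "colony",
    }
    required_before = {
        EventKind.APPEAR: ("away",),
        EventKind.VANISH: ("colony",),
        EventKind.NEST_ENTER: ("colony",),
        EventKind.NEST_EXIT: ("nest",),
    }
    # state before the first event, implied by its kind
    cur_state = required_before[first.kind][0]
    cur_t = first.t

    for e in events:
        if e is not first:
            if cur_state not in required_before[e.kind]:
                raise ValidationError(
                    f"individual {e.individual_id}: {e.kind.value} at t={e.t} "
                    f"while {cur_state}"
                )
            if e.t > cur_t:
                if cur_state == "colony":
                    segments.append(Bout(Category.COLONY, cur_t, e.t))
                elif cur_state == "nest":
                    segments.append(Bout(Category.NEST, cur_t, e.t))
                else:  # away
                    cat, food = _absence_category(
                        e.t - cur_t, stage, e.food_load, foraging_gap
                    )
                    segments.append(Bout(cat, cur_t, e.t, food))
        cur_state = state[e.kind]
        cur_t = e.t

    # Trailing span [last event, duration)
    if cur_t < duration:
        if cur_state == "colony":
            segments.append(Bout(Category.COLONY, cur_t, duration))
        elif cur_state == "nest":
            segments.append(Bout(Category.NEST, cur_t, duration))
        else:  # away, truncated by session end: no return observed
            cat, food = _absence_category(duration - cur_t, stage, None, foraging_gap)
            segments.append(Bout(cat, cur_t, duration, food))
            extrapolated = True

    seq = BoutSequence(_merge_adjacent(segments), duration)
    return DeriveResult(seq, extrapolated)


def bouts_to_events(
    seq: BoutSequence, stage: Stage, individual_id: str, sex: str = "F"
) -> list[EventRecord]:
    """Emit the minimal event stream whose derivation reproduces ``seq``.

    Transitions NEST<->COLONY become nest_exit/nest_enter and
    COLONY<->FORAGING become vanish/appear (with the food flag on appear
    during chick rearing).  NEST and FORAGING may never be adjacent — the
    colony-sandwich structure of real annotations.
    """
    stage = Stage(stage)
    events: list[EventRecord] = []
    for prev, cur in zip(seq.bouts, seq.bouts[1:]):
        t = cur.start
        pc, cc = prev.category, cur.category
        if {pc, cc} == {Category.NEST, Category.FORAGING}:
            raise ValidationError(
                f"NEST and FORAGING adjacent at t={t}: no colony transition to emit"
            )
        if pc is Category.NEST:
            kind, food = EventKind.NEST_EXIT, False
        elif pc is Category.FORAGING:
            kind = EventKind.APPEAR
            food = bool(prev.food) if stage is Stage.CHICK_REARING else False
        elif cc is Category.NEST:
            kind, food = EventKind.NEST_ENTER, False
        else:  # COLONY -> FORAGING
            kind, food = EventKind.VANISH, False
        events.append(
            EventRecord(t=t, kind=kind, individual_id=individual_id, sex=sex, food_load=food)
        )
    if not events:
        raise ValidationError(
            "single-bout sequence has no transitions; cannot emit an event stream"
        )
    return events


def _meta_path(path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".sessions" + path.suffix)


def write_session_table(sessions: Sequence[SessionRecord], path) -> None:
    """Write sessions as a long bout table plus a companion metadata table.

    ``path`` receives one row per bout (``session_id,individual_id,category,
    start_s,end_s,food``); session metadata goes to ``<stem>.sessions<ext>``
    next to it so the pair of files round-trips losslessly through
    :func:`read_session_table`.
    """
    rows, meta = [], []
    for s in sessions:
        if not isinstance(s, SessionRecord):
            raise ValidationError(f"not a SessionRecord: {s!r}")
        # SessionRecord construction already validated tiling; re-check spans.
        if s.bouts_f.duration != s.duration or s.bouts_m.duration != s.duration:
            raise ValidationError(f"session {s.session_id}: bouts do not tile the session")
        fid, mid = f"{s.pair_id}-F", f"{s.pair_id}-M"
        for ind, seq in ((fid, s.bouts_f), (mid, s.bouts_m)):
            for b in seq:
                rows.append(
                    {
                        "session_id": s.session_id,
                        "individual_id": ind,
                        "category": b.category.value,
                        "start_s": b.start,
                        "end_s": b.end,
                        "food": "" if b.food is None else str(b.food).lower(),
                    }
                )
        meta.append(
            {
                "session_id": s.session_id,
                "pair_id": s.pair_id,
                "year": s.year,
                "stage": s.stage.value,
                "phase": s.phase,
                "duration_s": s.duration,
                "female_id": fid,
                "male_id": mid,
                "extrapolated_f": str(s.extrapolated.get("F", False)).lower(),
                "extrapolated_m": str(s.extrapolated.get("M", False)).lower(),
            }
        )
    pd.DataFrame(rows, columns=BOUT_COLUMNS).to_csv(path, index=False)
    pd.DataFrame(meta, columns=META_COLUMNS).to_csv(_meta_path(path), index=False)


def read_session_table(path, meta_path=None) -> list[SessionRecord]:
    """Read the bout + metadata CSV pair written by :func:`write_session_table`."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _meta_path(path)
    bouts = pd.read_csv(path, keep_default_na=False)
    meta = pd.read_csv(meta_path, keep_default_na=False)
    sessions = []
    grouped = dict(tuple(bouts.groupby("session_id")))
    for _, m in meta.iterrows():
        sid = m["session_id"]
        if sid not in grouped:
            raise ValidationError(f"session {sid} in metadata but has no bouts")
        g = grouped[sid]
        seqs = {}
        for ind, sub in g.groupby("individual_id"):
            sub = sub.sort_values("start_s")
            blist = [
                Bout(
                    Category(r.category),
                    int(r.start_s),
                    int(r.end_s),
                    None if r.food == "" else r.food in ("true", "True", True),
                )
                for r in sub.itertuples()
            ]
            seqs[ind] = BoutSequence(blist, int(m["duration_s"]))
        try:
            bouts_f = seqs[m["female_id"]]
            bouts_m = seqs[m["male_id"]]
        except KeyError as exc:
            raise ValidationError(f"session {sid}: missing bouts for {exc}") from None
        sessions.append(
            SessionRecord(
                session_id=sid,
                pair_id=str(m["pair_id"]),
                year=int(m["year"]),
                stage=Stage(m["stage"]),
                phase=m["phase"],
                duration=int(m["duration_s"]),
                bouts_f=bouts_f,
                bouts_m=bouts_m,
                extrapolated={
                    "F": str(m["extrapolated_f"]).lower() == "true",
                    "M": str(m["extrapolated_m"]).lower() == "true",
                },
            )
        )
    return sessions
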