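"""Data model and I/O for continuous-report binocular-rivalry sessions.

A rivalry session is a set of 15-s trials in which the observer holds one of
three adjacent keys to report the currently dominant percept (happy face,
neutral face, or a mixed/piecemeal percept).  This module defines the raw
event containers (:class:`KeyEvent`, :class:`Trial`, :class:`Session`),
validation, and a tidy long-format CSV/JSON representation with a dialect
layer so logs from different acquisition setups can be adapted.

Times are seconds from trial onset throughout; milliseconds appear only at
the I/O boundary when a dialect requests them.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

PERCEPTS = ("happy", "neutral", "mixed")
MIMICRY_CONDITIONS = ("free", "blocked")
CONDITION_ORDERS = ("free-first", "blocked-first")

VALENCE_RANGE = (-3.0, 3.0)
AROUSAL_RANGE = (1.0, 7.0)


class EventLogError(ValueError):
    """Malformed event log: unknown key, bad times, or broken schema."""


class IntegrityError(EventLogError):
    """Conflicting metadata for the same (subject, condition, block, trial)."""


@dataclass(frozen=True)
class KeyEvent:
    """One press/release of a report key.

    ``t_release`` of ``None`` means the key was still held at trial end; it
    is imputed to the trial duration on load (hold-to-report semantics: the
    percept persisted until the stimulus disappeared).
    """

    key: str
    t_press: float
    t_release: float | None = None

    def __post_init__(self) -> None:
        if self.t_press < 0:
            raise EventLogError(f"t_press must be >= 0, got {self.t_press}")
        if self.t_release is not None and self.t_release <= self.t_press:
            raise EventLogError(
                f"t_release ({self.t_release}) must exceed t_press ({self.t_press})"
            )


@dataclass(frozen=True)
class KeyMap:
    """Bijection from the three physical keys onto percept labels.

    Exactly one key codes the mixed percept (in the original design the
    middle key always did).
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        labels = sorted(self.mapping.values())
        if labels != sorted(PERCEPTS):
            raise EventLogError(
                f"key map must be a bijection onto {PERCEPTS}, got {dict(self.mapping)}"
            )
        object.__setattr__(self, "mapping", dict(self.mapping))

    def percept(self, key: str) -> str:
        try:
            return self.mapping[key]
        except KeyError:
            raise EventLogError(f"unknown key symbol {key!r}; known: {sorted(self.mapping)}")

    def to_string(self) -> str:
        return ";".join(f"{k}:{v}" for k, v in sorted(self.mapping.items()))

    @classmethod
    def from_string(cls, s: str) -> "KeyMap":
        try:
            pairs = dict(item.split(":") for item in s.split(";"))
        except ValueError:
            raise EventLogError(f"cannot parse key map string {s!r}")
        return cls(pairs)


@dataclass
class Trial:
    """One 15-s rivalry presentation with its ordered key events."""

    subject_id: str
    mimicry: str
    block: int
    trial: int
    stimulus_id: str
    key_map: KeyMap
    duration_s: float = 15.0
    events: list[KeyEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mimicry not in MIMICRY_CONDITIONS:
            raise EventLogError(f"mimicry must be in {MIMICRY_CONDITIONS}, got {self.mimicry!r}")
        self.events = sorted(self.events, key=lambda e: (e.t_press, e.t_release or math.inf))

    @property
    def is_uncoded(self) -> bool:
        return len(self.events) == 0

    def key(self) -> tuple:
        return (self.subject_id, self.mimicry, self.block, self.trial)


@dataclass
class Rating:
    valence: float
    arousal: float


@dataclass
class Session:
    """All trials of one subject plus questionnaire scores and ratings.

    ``ratings`` is keyed by (mimicry, stimulus identity, expression); the
    valence scale is -3..+3 and arousal 1..7, matching the rating phase at
    the end of each mimicry condition.
    """

    subject_id: str
    condition_order: str
    trials: list[Trial] = field(default_factory=list)
    tas20_total: float | None = None
    iri_total: float | None = None
    ratings: dict[tuple[str, str, str], Rating] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition_order not in CONDITION_ORDERS:
            raise EventLogError(
                f"condition_order must be in {CONDITION_ORDERS}, got {self.condition_order!r}"
            )
        if len(self.trials) > 32:
            raise EventLogError(
                f"subject {self.subject_id}: {len(self.trials)} trials exceeds the "
                "2 conditions x 2 blocks x 8 trials design maximum of 32"
            )
        for (mim, _stim, _expr), r in self.ratings.items():
            if not (VALENCE_RANGE[0] <= r.valence <= VALENCE_RANGE[1]):
                raise EventLogError(f"valence {r.valence} outside {VALENCE_RANGE}")
            if not (AROUSAL_RANGE[0] <= r.arousal <= AROUSAL_RANGE[1]):
                raise EventLogError(f"arousal {r.arousal} outside {AROUSAL_RANGE}")
            if mim not in MIMICRY_CONDITIONS:
                raise EventLogError(f"rating condition {mim!r} unknown")


@dataclass(frozen=True)
class Dialect:
    """Column names and units of a concrete event-log format.

    The defaults describe this package's own tidy long format (one row per
    key event; uncoded trials appear as a single row with empty key/time
    fields).  ``time_unit`` may be "s" or "ms".  ``report_mode`` is carried
    here so a log can declare whether keys were held ("hold") or toggled
    ("toggle"); the metrics layer consumes it.
    """

    subject: str = "subject"
    condition_order: str = "condition_order"
    mimicry: str = "mimicry"
    block: str = "block"
    trial: str = "trial"
    stimulus: str = "stimulus"
    key: str = "key"
    key_map: str = "key_map"
    t_press: str = "t_press"
    t_release: str = "t_release"
    duration: str = "duration_s"
    time_unit: str = "s"
    report_mode: str = "hold"

    def to_seconds(self, value: float) -> float:
        return value / 1000.0 if self.time_unit == "ms" else value

    def from_seconds(self, value: float) -> float:
        return value * 1000.0 if self.time_unit == "ms" else value


@dataclass
class Issue:
    severity: str  # "error" | "warning"
    trial: tuple | None
    message: str


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    if isinstance(v, str) and v.strip() == "":
        return True
    return False


def read_event_log(path: str | os.PathLike, dialect: Dialect | None = None) -> list[Session]:
    """Read sessions from an events CSV (or JSON), plus optional sidecars.

    ``path`` may point at the events CSV itself or at a directory containing
    ``events.csv`` and, optionally, ``subjects.csv`` (questionnaire totals,
    condition order) and ``ratings.csv``.  A ``.json`` path is read as the
    nested single-file alternative written by :func:`write_sessions`.

    Row order is irrelevant: events are sorted on load.  A missing release
    time is imputed at the trial duration.
    """
    dialect = dialect or Dialect()
    path = os.fspath(path)
    if path.endswith(".json"):
        with open(path) as fh:
            return sessions_from_json(json.load(fh))
    if os.path.isdir(path):
        events_path = os.path.join(path, "events.csv")
        subjects_path = os.path.join(path, "subjects.csv")
        ratings_path = os.path.join(path, "ratings.csv")
    else:
        events_path = path
        base = os.path.dirname(path)
        subjects_path = os.path.join(base, "subjects.csv")
        ratings_path = os.path.join(base, "ratings.csv")
    if not os.path.exists(events_path):
        raise FileNotFoundError(events_path)

    df = pd.read_csv(events_path, dtype={dialect.subject: str, dialect.stimulus: str})
    required = [dialect.subject, dialect.mimicry, dialect.block, dialect.trial,
                dialect.stimulus, dialect.key_map, dialect.key,
                dialect.t_press, dialect.t_release]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise EventLogError(f"event log missing columns {missing_cols}")

    trials: dict[tuple, Trial] = {}
    trial_meta: dict[tuple, tuple] = {}
    session_order: dict[str, str] = {}
    for idx, row in df.iterrows():
        subj = str(row[dialect.subject])
        key_map = KeyMap.from_string(str(row[dialect.key_map]))
        duration = float(row[dialect.duration]) if dialect.duration in df.columns else 15.0
        duration = dialect.to_seconds(duration) if dialect.time_unit == "ms" else duration
        tkey = (subj, str(row[dialect.mimicry]), int(row[dialect.block]), int(row[dialect.trial]))
        meta = (str(row[dialect.stimulus]), key_map.to_string(), duration)
        if tkey in trial_meta and trial_meta[tkey] != meta:
            raise IntegrityError(
                f"row {idx}: conflicting metadata for trial {tkey}: "
                f"{meta} vs {trial_meta[tkey]}"
            )
        if tkey not in trials:
            trial_meta[tkey] = meta
            trials[tkey] = Trial(
                subject_id=subj, mimicry=tkey[1], block=tkey[2], trial=tkey[3],
                stimulus_id=meta[0], key_map=key_map, duration_s=duration, events=[],
            )
        if dialect.condition_order in df.columns and not _is_missing(row[dialect.condition_order]):
            session_order[subj] = str(row[dialect.condition_order])

        if _is_missing(row[dialect.key]):
            continue  # uncoded-trial placeholder row
        key = str(row[dialect.key])
        if key not in key_map.mapping:
            raise EventLogError(
                f"row {idx}: unknown key symbol {key!r} for trial {tkey}; "
                f"key map is {key_map.to_string()}"
            )
        t_press = dialect.to_seconds(float(row[dialect.t_press]))
        if _is_missing(row[dialect.t_release]):
            t_release = duration  # held to trial end
        else:
            t_release = dialect.to_seconds(float(row[dialect.t_release]))
        if t_release <= t_press:
            raise EventLogError(
                f"row {idx}: t_release ({t_release}) <= t_press ({t_press}) for trial {tkey}"
            )
        trials[tkey].events.append(KeyEvent(key, t_press, t_release))

    subj_info: dict[str, dict] = {}
    if os.path.exists(subjects_path):
        sdf = pd.read_csv(subjects_path, dtype={"subject": str})
        for _, row in sdf.iterrows():
            subj_info[str(row["subject"])] = {
                "condition_order": row.get("condition_order"),
                "tas20_total": None if _is_missing(row.get("tas20_total")) else float(row["tas20_total"]),
                "iri_total": None if _is_missing(row.get("iri_total")) else float(row["iri_total"]),
            }

    ratings: dict[str, dict] = {}
    if os.path.exists(ratings_path):
        rdf = pd.read_csv(ratings_path, dtype={"subject": str, "stimulus": str})
        for _, row in rdf.iterrows():
            ratings.setdefault(str(row["subject"]), {})[
                (str(row["mimicry"]), str(row["stimulus"]), str(row["expression"]))
            ] = Rating(float(row["valence"]), float(row["arousal"]))

    sessions = []
    for subj in sorted({t.subject_id for t in trials.values()}):
        strials = sorted(
            (t for t in trials.values() if t.subject_id == subj),
            key=lambda t: (t.block, t.trial),
        )
        for t in strials:
            t.events = sorted(t.events, key=lambda e: (e.t_press, e.t_release or math.inf))
        info = subj_info.get(subj, {})
        order = info.get("condition_order") or session_order.get(subj)
        if _is_missing(order):
            order = _infer_order(strials)
        sessions.append(Session(
            subject_id=subj,
            condition_order=str(order),
            trials=strials,
            tas20_total=info.get("tas20_total"),
            iri_total=info.get("iri_total"),
            ratings=ratings.get(subj, {}),
        ))
    return sessions


def _infer_order(trials: Sequence[Trial]) -> str:
    first = min(trials, key=lambda t: (t.block, t.trial))
    return "free-first" if first.mimicry == "free" else "blocked-first"


def validate_session(session: Session) -> list[Issue]:
    """Report invariant violations; empty list iff the session is clean.

    Trials without any key event are flagged as "uncoded" warnings rather
    than errors: observers occasionally fail to report a whole trial and the
    analysis simply drops that trial from its denominators.
    """
    issues: list[Issue] = []
    seen: set[tuple] = set()
    for t in session.trials:
        tk = t.key()
        if tk in seen:
            issues.append(Issue("error", tk, "duplicate trial key"))
        seen.add(tk)
        if t.is_uncoded:
            issues.append(Issue("warning", tk, "uncoded trial (no key events)"))
        for ev in t.events:
            if ev.key not in t.key_map.mapping:
                issues.append(Issue("error", tk, f"unknown key {ev.key!r}"))
            if ev.t_press > t.duration_s:
                issues.append(Issue("error", tk, f"t_press {ev.t_press} exceeds duration {t.duration_s}"))
            rel = ev.t_release if ev.t_release is not None else t.duration_s
            if rel > t.duration_s + 1e-9:
                issues.append(Issue("error", tk, f"t_release {rel} exceeds duration {t.duration_s}"))
    return issues


# ---------------------------------------------------------------------------
# writing

def sessions_to_frames(sessions: Iterable[Session], dialect: Dialect | None = None):
    """Long-format frames (events, subjects, ratings) for a list of sessions."""
    dialect = dialect or Dialect()
    ev_rows, subj_rows, rat_rows = [], [], []
    for s in sessions:
        subj_rows.append({
            "subject": s.subject_id, "condition_order": s.condition_order,
            "tas20_total": s.tas20_total, "iri_total": s.iri_total,
        })
        for (mim, stim, expr), r in sorted(s.ratings.items()):
            rat_rows.append({
                "subject": s.subject_id, "mimicry": mim, "stimulus": stim,
                "expression": expr, "valence": r.valence, "arousal": r.arousal,
            })
        for t in s.trials:
            base = {
                dialect.subject: s.subject_id,
                dialect.condition_order: s.condition_order,
                dialect.mimicry: t.mimicry, dialect.block: t.block,
                dialect.trial: t.trial, dialect.stimulus: t.stimulus_id,
                dialect.key_map: t.key_map.to_string(),
                dialect.duration: dialect.from_seconds(t.duration_s)
                if dialect.time_unit == "ms" else t.duration_s,
            }
            if t.is_uncoded:
                ev_rows.append({**base, dialect.key: "",
                                dialect.t_press: math.nan, dialect.t_release: math.nan})
            for ev in t.events:
                ev_rows.append({**base, dialect.key: ev.key,
                                dialect.t_press: dialect.from_seconds(ev.t_press),
                                dialect.t_release: math.nan if ev.t_release is None
                                else dialect.from_seconds(ev.t_release)})
    cols = [dialect.subject, dialect.condition_order, dialect.mimicry, dialect.block,
            dialect.trial, dialect.stimulus, dialect.key_map, dialect.duration,
            dialect.key, dialect.t_press, dialect.t_release]
    events = pd.DataFrame(ev_rows, columns=cols)
    subjects = pd.DataFrame(subj_rows, columns=["subject", "condition_order",
                                                "tas20_total", "iri_total"])
    rat_cols = ["subject", "mimicry", "stimulus", "expression", "valence", "arousal"]
    ratings = pd.DataFrame(rat_rows, columns=rat_cols)
    return events, subjects, ratings


def write_sessions(sessions: Iterable[Session], out_dir: str | os.PathLike,
                   dialect: Dialect | None = None) -> dict[str, str]:
    """Write events.csv / subjects.csv / ratings.csv; returns the paths."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    events, subjects, ratings = sessions_to_frames(sessions, dialect)
    paths = {}
    for name, frame in [("events", events), ("subjects", subjects), ("ratings", ratings)]:
        p = os.path.join(out_dir, f"{name}.csv")
        frame.to_csv(p, index=False, float_format="%.9f")
        paths[name] = p
    return paths


def sessions_to_json(sessions: Iterable[Session]) -> list[dict]:
    out = []
    for s in sessions:
        out.append({
            "subject": s.subject_id, "condition_order": s.condition_order,
            "tas20_total": s.tas20_total, "iri_total": s.iri_total,
            "ratings": [
                {"mimicry": m, "stimulus": st, "expression": e,
                 "valence": r.valence, "arousal": r.arousal}
                for (m, st, e), r in sorted(s.ratings.items())
            ],
            "trials": [
                {"mimicry": t.mimicry, "block": t.block, "trial": t.trial,
                 "stimulus": t.stimulus_id, "key_map": t.key_map.to_string(),
                 "duration_s": t.duration_s,
                 "events": [dataclasses.asdict(ev) for ev in t.events]}
                for t in s.trials
            ],
        })
    return out


def sessions_from_json(payload: list[dict]) -> list[Session]:
    sessions = []
    for s in payload:
        trials = []
        for t in s["trials"]:
            duration = float(t.get("duration_s", 15.0))
            events = []
            for ev in t["events"]:
                rel = ev.get("t_release")
                events.append(KeyEvent(ev["key"], float(ev["t_press"]),
                                       duration if rel is None else float(rel)))
            trials.append(Trial(
                subject_id=str(s["subject"]), mimicry=t["mimicry"], block=int(t["block"]),
                trial=int(t["trial"]), stimulus_id=str(t["stimulus"]),
                key_map=KeyMap.from_string(t["key_map"]), duration_s=duration,
                events=events,
            ))
        ratings = {
            (r["mimicry"], str(r["stimulus"]), r["expression"]):
                Rating(float(r["valence"]), float(r["arousal"]))
            for r in s.get("ratings", [])
        }
        sessions.append(Session(
            subject_id=str(s["subject"]), condition_order=s["condition_order"],
            trials=trials, tas20_total=s.get("tas20_total"),
            iri_total=s.get("iri_total"), ratings=ratings,
        ))
    return sessions


def write_json(sessions: Iterable[Session], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(sessions_to_json(sessions), fh, indent=1)
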