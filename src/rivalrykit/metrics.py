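"""Percept-dominance metrics for continuous-report rivalry trials.

Keypress events are first resolved into non-overlapping dominance intervals
and then reduced to the three standard components of a rivalry time course:

* **IP** (initial percept) — the first *non-mixed* percept reported in a
  trial (happy or neutral); mixed reports are skipped because they reflect
  unresolved competition, not a winner.
* **ORT** (onset resolution time) — the onset time of the IP interval, i.e.
  how long the visual system took to resolve the ambiguity.
* **CT** (cumulative time) — total dominance duration per percept within a
  trial, an index of perceptual predominance/stabilization.

Two report conventions are supported.  Under the default *hold-to-report*
convention a percept is dominant while its key is held, with last-key-wins
on overlapping holds; gaps are unreported time.  Under *toggle* each press
switches the report until the next press.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .events import PERCEPTS, Session, Trial

ORT_FLOOR_S = 1e-3  # a press at exactly trial onset is floored before log


@dataclass(frozen=True)
class PerceptInterval:
    label: str
    t_on: float
    t_off: float

    def __post_init__(self) -> None:
        if not (self.t_on < self.t_off):
            raise ValueError(f"interval must have t_on < t_off, got [{self.t_on}, {self.t_off}]")

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on


@dataclass
class TrialMetrics:
    """IP, ORT and per-label CT for one trial.

    ``ip`` is "none" and ``ort_s`` is None for uncoded trials or trials in
    which only mixed percepts were reported.  CT values plus unreported time
    always sum to the trial duration.
    """

    ip: str
    ort_s: float | None
    ct_s: dict[str, float]
    unreported_s: float


@dataclass
class SubjectCell:
    """Per subject x mimicry x label aggregate over coded trials.

    ``mean_ort_s`` averages ORT over trials whose IP equals ``label`` (so it
    is meaningful only for happy/neutral); ``mean_ct_s`` averages CT over
    all coded trials of the cell's condition.
    """

    subject_id: str
    mimicry: str
    label: str
    mean_ct_s: float
    mean_ort_s: float | None
    ip_count: int
    n_trials_used: int
    log_mean_ort_s: float | None = None


def events_to_intervals(trial: Trial, mode: str | None = None) -> list[PerceptInterval]:
    """Resolve key events into non-overlapping, time-ordered dominance intervals.

    Hold mode: at any moment the dominant label is that of the most recent
    still-held press (a new press truncates the open interval; when that key
    is released an earlier, still-held key resumes).  Toggle mode: a press
    switches the report until the next press or trial end; releases are
    ignored.  Intervals are clipped to [0, duration] and zero-length pieces
    dropped.
    """
    mode = mode or "hold"
    if mode not in ("hold", "toggle"):
        raise ValueError(f"unknown report mode {mode!r}")
    duration = trial.duration_s
    events = sorted(trial.events, key=lambda e: e.t_press)
    if not events:
        return []

    if mode == "toggle":
        segments = []
        for i, ev in enumerate(events):
            t_on = ev.t_press
            t_off = events[i + 1].t_press if i + 1 < len(events) else duration
            segments.append((trial.key_map.percept(ev.key), t_on, t_off))
        return _clip_merge(segments, duration)

    # hold-to-report: sweep over press/release boundaries, tracking held keys
    boundaries: list[tuple[float, int, int]] = []  # (time, kind, event index); kind 0=release first
    for i, ev in enumerate(events):
        rel = ev.t_release if ev.t_release is not None else duration
        boundaries.append((ev.t_press, 1, i))
        boundaries.append((rel, 0, i))
    boundaries.sort(key=lambda b: (b[0], b[1]))

    held: set[int] = set()
    segments: list[tuple[str, float, float]] = []
    cur_label: str | None = None
    cur_on = 0.0
    for t, kind, i in boundaries:
        # dominant = most recent press among held; ties broken by event order
        if kind == 1:
            held.add(i)
        else:
            held.discard(i)
        dom = max(held, key=lambda j: (events[j].t_press, j), default=None)
        new_label = trial.key_map.percept(events[dom].key) if dom is not None else None
        if new_label != cur_label:
            if cur_label is not None and t > cur_on:
                segments.append((cur_label, cur_on, t))
            cur_label, cur_on = new_label, t
    if cur_label is not None and duration > cur_on:
        segments.append((cur_label, cur_on, duration))
    return _clip_merge(segments, duration)


def _clip_merge(segments: Sequence[tuple[str, float, float]], duration: float) -> list[PerceptInterval]:
    clipped = []
    for label, t_on, t_off in segments:
        t_on, t_off = max(0.0, t_on), min(duration, t_off)
        if t_off - t_on > 0:
            clipped.append((label, t_on, t_off))
    # merge adjacent same-label segments (can arise from clipping)
    merged: list[list] = []
    for seg in clipped:
        if merged and merged[-1][0] == seg[0] and abs(merged[-1][2] - seg[1]) < 1e-12:
            merged[-1][2] = seg[2]
        else:
            merged.append(list(seg))
    return [PerceptInterval(*m) for m in merged]


def initial_percept(intervals: Sequence[PerceptInterval]) -> str:
    """Label of the first non-mixed interval; "none" if there is no such interval."""
    for iv in intervals:
        if iv.label != "mixed":
            return iv.label
    return "none"


def onset_resolution_time(intervals: Sequence[PerceptInterval]) -> float | None:
    """Onset time of the initial percept; None when no non-mixed percept occurred."""
    for iv in intervals:
        if iv.label != "mixed":
            return iv.t_on
    return None


def cumulative_times(intervals: Sequence[PerceptInterval], duration: float) -> tuple[dict[str, float], float]:
    """Per-label dominance sums and the unreported remainder of the trial."""
    ct = {label: 0.0 for label in PERCEPTS}
    for iv in intervals:
        ct[iv.label] += iv.duration
    unreported = duration - sum(ct.values())
    return ct, unreported


def trial_metrics(trial: Trial, mode: str | None = None) -> TrialMetrics:
    intervals = events_to_intervals(trial, mode=mode)
    ct, unreported = cumulative_times(intervals, trial.duration_s)
    return TrialMetrics(
        ip=initial_percept(intervals),
        ort_s=onset_resolution_time(intervals),
        ct_s=ct,
        unreported_s=unreported,
    )


def metrics_table(sessions: Iterable[Session], mode: str | None = None) -> pd.DataFrame:
    """Trial-level metrics table: one row per trial, uncoded trials flagged."""
    rows = []
    for s in sessions:
        for t in s.trials:
            m = trial_metrics(t, mode=mode)
            rows.append({
                "subject": s.subject_id, "mimicry": t.mimicry, "block": t.block,
                "trial": t.trial, "stimulus": t.stimulus_id,
                "uncoded": t.is_uncoded,
                "ip": m.ip, "ort_s": math.nan if m.ort_s is None else m.ort_s,
                "ct_happy_s": m.ct_s["happy"], "ct_neutral_s": m.ct_s["neutral"],
                "ct_mixed_s": m.ct_s["mixed"], "unreported_s": m.unreported_s,
            })
    cols = ["subject", "mimicry", "block", "trial", "stimulus", "uncoded", "ip",
            "ort_s", "ct_happy_s", "ct_neutral_s", "ct_mixed_s", "unreported_s"]
    return pd.DataFrame(rows, columns=cols)


def summarize_subject(sessions: Iterable[Session], mode: str | None = None) -> list[SubjectCell]:
    """Aggregate trial metrics into subject x mimicry x label cells.

    Uncoded trials are excluded from all denominators (absence of a report
    is not evidence of absence of a percept).  CT means run over all coded
    trials of the condition; ORT means run only over trials whose IP equals
    the cell's label, so they exist only for happy/neutral and only when at
    least one such trial occurred.
    """
    table = metrics_table(sessions, mode=mode)
    cells: list[SubjectCell] = []
    for (subj, mim), grp in table.groupby(["subject", "mimicry"], sort=True):
        coded = grp[~grp["uncoded"]]
        n_used = len(coded)
        for label in PERCEPTS:
            mean_ct = float(coded[f"ct_{label}_s"].mean()) if n_used else math.nan
            if label == "mixed":
                mean_ort, ip_count = None, 0
            else:
                sel = coded[coded["ip"] == label]
                ip_count = len(sel)
                mean_ort = float(sel["ort_s"].mean()) if ip_count else None
            cells.append(SubjectCell(
                subject_id=subj, mimicry=mim, label=label,
                mean_ct_s=mean_ct, mean_ort_s=mean_ort,
                ip_count=ip_count, n_trials_used=n_used,
            ))
    return cells


def apply_ort_exclusions(cells: Sequence[SubjectCell]) -> tuple[list[str], list[str]]:
    """Split subjects into (kept, excluded) for the ORT analysis.

    A subject enters the mimicry x IP ANOVA on ORT only with all four cells
    (2 conditions x {happy, neutral}) populated; a subject missing any IP
    type in any condition is excluded.  CT analyses keep every subject.
    """
    by_subject: dict[str, list[SubjectCell]] = {}
    for c in cells:
        by_subject.setdefault(c.subject_id, []).append(c)
    kept, excluded = [], []
    for subj in sorted(by_subject):
        ok = True
        for mim in ("free", "blocked"):
            for label in ("happy", "neutral"):
                n = sum(c.ip_count for c in by_subject[subj]
                        if c.mimicry == mim and c.label == label)
                if n == 0:
                    ok = False
        (kept if ok else excluded).append(subj)
    return kept, excluded


def log_transform_ort(cells: Sequence[SubjectCell]) -> list[SubjectCell]:
    """Attach the natural log of mean ORT (seconds); originals retained.

    A mean ORT of exactly zero (a press at trial onset) is floored to 1 ms
    before the log; negative values cannot arise from valid intervals and
    raise.
    """
    out = []
    for c in cells:
        if c.mean_ort_s is None:
            out.append(replace(c, log_mean_ort_s=None))
            continue
        if c.mean_ort_s < 0:
            raise ValueError(f"negative mean ORT {c.mean_ort_s} for subject {c.subject_id}")
        out.append(replace(c, log_mean_ort_s=math.log(max(c.mean_ort_s, ORT_FLOOR_S))))
    return out


def cells_table(cells: Sequence[SubjectCell]) -> pd.DataFrame:
    rows = [{
        "subject": c.subject_id, "mimicry": c.mimicry, "label": c.label,
        "mean_ct_s": c.mean_ct_s,
        "mean_ort_s": math.nan if c.mean_ort_s is None else c.mean_ort_s,
        "log_mean_ort_s": math.nan if c.log_mean_ort_s is None else c.log_mean_ort_s,
        "ip_count": c.ip_count, "n_trials_used": c.n_trials_used,
    } for c in cells]
    return pd.DataFrame(rows, columns=["subject", "mimicry", "label", "mean_ct_s",
                                       "mean_ort_s", "log_mean_ort_s", "ip_count",
                                       "n_trials_used"])


def write_tidy_tables(sessions: Sequence[Session], out_dir, mode: str | None = None) -> dict[str, str]:
    """Write session CSVs plus trial-level and subject-level metric tables."""
    import os

    from .events import write_sessions

    paths = write_sessions(sessions, out_dir)
    os.makedirs(out_dir, exist_ok=True)
    tm = metrics_table(sessions, mode=mode)
    p = os.path.join(os.fspath(out_dir), "trial_metrics.csv")
    tm.to_csv(p, index=False, float_format="%.9f")
    paths["trial_metrics"] = p
    cells = log_transform_ort(summarize_subject(sessions, mode=mode))
    p = os.path.join(os.fspath(out_dir), "subject_cells.csv")
    cells_table(cells).to_csv(p, index=False, float_format="%.9f")
    paths["subject_cells"] = p
    return paths


# field access used in docstrings/tests
__all__ = [
    "PerceptInterval", "TrialMetrics", "SubjectCell", "events_to_intervals",
    "initial_percept", "onset_resolution_time", "cumulative_times",
    "trial_metrics", "metrics_table", "summarize_subject",
    "apply_ort_exclusions", "log_transform_ort", "cells_table",
    "write_tidy_tables", "ORT_FLOOR_S",
]
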