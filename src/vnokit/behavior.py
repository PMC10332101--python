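"""Investigation-bout scoring and the log2 preference statistic.

Each session gives a test mouse 10 min to investigate two stimulus sources
(labelled A and B; in the assays these are the healthy-condition and
sick-condition stimuli).  Manual scoring yields investigation bouts; the
preference score is ``log2(IT_A / IT_B)`` of the summed bout durations.
Positive scores mean preference for source A.  The group statistic is the
mean of *per-animal* scores — not the score of the group-mean times — with
a two-sided one-sample t-test against zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import DataError, sem
from .stats import TestResult, one_sample_vs_zero

LABELS = ("A", "B")


@dataclass
class Bout:
    label: str
    start_s: float
    stop_s: float

    def __post_init__(self) -> None:
        if self.stop_s <= self.start_s:
            raise DataError(f"bout stop ({self.stop_s}) must exceed start ({self.start_s})")

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s


@dataclass
class BehaviorSession:
    subject_id: str
    bouts: list[Bout] = field(default_factory=list)
    session_length_s: float = 600.0

    def __post_init__(self) -> None:
        for b in self.bouts:
            if b.start_s < 0 or b.stop_s > self.session_length_s:
                raise DataError(
                    f"subject {self.subject_id}: bout [{b.start_s}, {b.stop_s}) outside session"
                )
        ordered = sorted(self.bouts, key=lambda b: b.start_s)
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.start_s < prev.stop_s:
                raise DataError(f"subject {self.subject_id}: overlapping bouts")


@dataclass
class PreferenceScore:
    subject_id: str
    it_a: float
    it_b: float
    score: float
    epsilon_applied: bool = False


def investigation_times(session: BehaviorSession) -> tuple[float, float]:
    """Summed bout duration per stimulus label (IT_A, IT_B) in seconds."""
    totals = {lab: 0.0 for lab in LABELS}
    for b in session.bouts:
        if b.label not in totals:
            raise DataError(f"unknown stimulus label {b.label!r}")
        totals[b.label] += b.duration_s
    return totals["A"], totals["B"]


def preference_score(
    it_a: float, it_b: float, zero_policy: str = "strict", epsilon_s: float = 0.5
) -> tuple[float, bool]:
    """log2 investigation-time ratio; positive favours source A.

    Undefined when either time is zero: the strict policy (default) raises,
    the ``"epsilon"`` policy adds ``epsilon_s`` to both times and flags it.
    """
    if it_a < 0 or it_b < 0:
        raise ValueError("investigation times must be non-negative")
    flagged = False
    if it_a == 0 or it_b == 0:
        if zero_policy == "strict":
            raise DataError("zero investigation time: log2 ratio undefined (strict policy)")
        elif zero_policy == "epsilon":
            it_a, it_b = it_a + epsilon_s, it_b + epsilon_s
            flagged = True
        else:
            raise ValueError(f"unknown zero policy {zero_policy!r}")
    # log difference rather than log of the ratio: label swap then negates
    # the score exactly in floating point
    return math.log2(it_a) - math.log2(it_b), flagged


def score_session(
    session: BehaviorSession, zero_policy: str = "strict", epsilon_s: float = 0.5
) -> PreferenceScore:
    it_a, it_b = investigation_times(session)
    score, flagged = preference_score(it_a, it_b, zero_policy, epsilon_s)
    return PreferenceScore(session.subject_id, it_a, it_b, score, flagged)


@dataclass
class GroupPreference:
    mean: float
    sem: Optional[float]
    test: TestResult
    n: int


def group_preference(scores: Sequence[float]) -> GroupPreference:
    """Mean +/- SEM of per-animal scores and a one-sample t-test vs 0."""
    s = np.asarray(scores, dtype=float)
    if len(s) < 2:
        raise DataError("at least 2 subjects are required")
    return GroupPreference(float(s.mean()), sem(s), one_sample_vs_zero(s), len(s))


# -- bout table I/O ---------------------------------------------------------

BOUT_COLUMNS = ("subject_id", "label", "start_s", "stop_s")


def read_bout_table(path) -> list[BehaviorSession]:
    """Read a delimited bout log (subject_id, label, start_s, stop_s)."""
    df = pd.read_csv(path)
    missing = [c for c in BOUT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"bout table {path}: missing columns {missing}")
    return sessions_from_table(df)


def sessions_from_table(df: pd.DataFrame, session_length_s: float = 600.0) -> list[BehaviorSession]:
    out = []
    for subject, grp in df.groupby("subject_id", sort=True):
        bouts = [
            Bout(str(r.label), float(r.start_s), float(r.stop_s)) for r in grp.itertuples()
        ]
        out.append(BehaviorSession(str(subject), bouts, session_length_s))
    return out


def sessions_to_table(sessions: Sequence[BehaviorSession]) -> pd.DataFrame:
    rows = [
        {"subject_id": s.subject_id, "label": b.label, "start_s": b.start_s, "stop_s": b.stop_s}
        for s in sessions
        for b in s.bouts
    ]
    return pd.DataFrame(rows, columns=list(BOUT_COLUMNS))


def bouts_from_events(events: pd.DataFrame) -> pd.DataFrame:
    """Convert point start/stop event rows into bout rows.

    Expects columns subject_id, label, time_s, event ('start' or 'stop');
    events must alternate start/stop per (subject, label) stream.
    """
    rows = []
    for (subject, label), grp in events.groupby(["subject_id", "label"], sort=True):
        grp = grp.sort_values("time_s")
        open_t: Optional[float] = None
        for r in grp.itertuples():
            if r.event == "start":
                if open_t is not None:
                    raise DataError(f"subject {subject}: two starts without a stop")
                open_t = float(r.time_s)
            elif r.event == "stop":
                if open_t is None:
                    raise DataError(f"subject {subject}: stop without a start")
                rows.append(
                    {"subject_id": subject, "label": label, "start_s": open_t,
                     "stop_s": float(r.time_s)}
                )
                open_t = None
            else:
                raise DataError(f"unknown event type {r.event!r}")
        if open_t is not None:
            raise DataError(f"subject {subject}: unclosed bout at {open_t}")
    return pd.DataFrame(rows, columns=list(BOUT_COLUMNS))
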