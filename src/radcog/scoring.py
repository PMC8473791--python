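"""Behavioral scores for the attentional set-shifting test (ATSET).

The assay presents a rat with up to 30 digging trials per day, at most two
days per stage; the stage is passed ("criterion reached") once the animal
succeeds in six consecutive attempts.  Three scores summarise a stage:

ATRC
    Attempts to reach criterion: the number of attempts (correct plus
    incorrect) taken on day 1 if the criterion is reached that day,
    otherwise 30 plus the number of day-2 attempts.  Lower is better.
FR
    Failure ratio: incorrect attempts over total attempts, pooled across
    both days.  Lies in [0, 1).
MCL
    Mean correct latency: the average time of the successful attempts, in
    seconds.  If day 1 was failed, only day-2 successes count.

A subject that never reaches criterion keeps defined scores (ATRC counts
all 30 + day-2 attempts) but carries a ``criterion_unmet`` flag so that
downstream analyses can exclude it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

PRESCREEN_STAGES: tuple[str, ...] = ("SD", "CD", "CDR", "IDS")
POST_STAGES: tuple[str, ...] = ("SD", "CD", "CDR", "IDS", "IDR", "EDS", "EDR")
IONS: tuple[str, ...] = ("sham", "He", "O", "Si", "Ti", "Fe")

MAX_TRIALS_PER_DAY = 30
CRITERION_RUN = 6


class ProtocolError(ValueError):
    """A trial sequence violates the stage protocol."""


@dataclass(frozen=True)
class TrialRecord:
    """One attempt: correct flag plus latency (recorded for correct attempts)."""

    correct: bool
    latency_s: float | None = None

    def __post_init__(self) -> None:
        if self.latency_s is not None and not self.correct:
            raise ProtocolError("latency recorded for an incorrect attempt")
        if self.latency_s is not None and self.latency_s <= 0:
            raise ProtocolError(f"non-positive latency {self.latency_s}")


def _day_reaches_criterion(day: Sequence[TrialRecord]) -> bool:
    """A day ends in success iff its final six attempts are all correct."""
    return len(day) >= CRITERION_RUN and all(t.correct for t in day[-CRITERION_RUN:])


@dataclass
class StagePerformance:
    """A subject's full attempt sequence for one stage (at most two days)."""

    stage: str
    day1: list[TrialRecord]
    day2: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.day1:
            raise ProtocolError(f"stage {self.stage}: empty day-1 sequence")
        for label, day in (("day1", self.day1), ("day2", self.day2)):
            if len(day) > MAX_TRIALS_PER_DAY:
                raise ProtocolError(
                    f"stage {self.stage}: {label} has {len(day)} attempts "
                    f"(max {MAX_TRIALS_PER_DAY})"
                )
        if self.day2 and _day_reaches_criterion(self.day1):
            raise ProtocolError(
                f"stage {self.stage}: day-2 attempts present although the "
                "day-1 criterion was reached"
            )

    @property
    def criterion_day1(self) -> bool:
        return _day_reaches_criterion(self.day1)

    @property
    def reached_criterion(self) -> bool:
        return self.criterion_day1 or _day_reaches_criterion(self.day2)

    @property
    def n_attempts(self) -> int:
        return len(self.day1) + len(self.day2)


@dataclass(frozen=True)
class ScoreSet:
    """Derived {ATRC, FR, MCL} for one stage; ``mcl_s`` may be absent."""

    atrc: int
    fr: float
    mcl_s: float | None
    criterion_unmet: bool = False


@dataclass
class Subject:
    """One animal: arm assignment plus per-stage trial sequences."""

    subject_id: str
    ion: str
    dose_cgy: float
    prescreen: dict[str, StagePerformance] = field(default_factory=dict)
    post: dict[str, StagePerformance] = field(default_factory=dict)


def compute_atrc(perf: StagePerformance) -> int:
    """Attempts to reach criterion; 30 + day-2 attempts when day 1 is failed."""
    perf.validate()
    if perf.criterion_day1:
        return len(perf.day1)
    return MAX_TRIALS_PER_DAY + len(perf.day2)


def compute_fr(perf: StagePerformance) -> float:
    """Failure ratio: incorrect over total attempts across both days."""
    perf.validate()
    total = perf.n_attempts
    if total == 0:
        raise ProtocolError("failure ratio undefined with zero attempts")
    incorrect = sum(1 for t in perf.day1 + perf.day2 if not t.correct)
    return incorrect / total


def compute_mcl(perf: StagePerformance) -> float | None:
    """Mean latency over qualifying successes; day-2 only when day 1 failed.

    Returns None when no qualifying attempt carries a latency (the score is
    *absent*, never coerced to zero).
    """
    perf.validate()
    window = perf.day1 + perf.day2 if perf.criterion_day1 else perf.day2
    latencies = [t.latency_s for t in window if t.correct and t.latency_s is not None]
    if not latencies:
        return None
    return sum(latencies) / len(latencies)


def score_stage(perf: StagePerformance) -> ScoreSet:
    return ScoreSet(
        atrc=compute_atrc(perf),
        fr=compute_fr(perf),
        mcl_s=compute_mcl(perf),
        criterion_unmet=not perf.reached_criterion,
    )


def score_subject(subject: Subject) -> dict[str, dict[str, ScoreSet]]:
    """Score every present stage; absent stages stay missing."""
    return {
        "prescreen": {s: score_stage(p) for s, p in subject.prescreen.items()},
        "post": {s: score_stage(p) for s, p in subject.post.items()},
    }


# ---------------------------------------------------------------------------
# Tabular interchange

SCORES_COLUMNS = [
    "subject_id",
    "ion",
    "dose_cgy",
    "phase",
    "stage",
    "atrc",
    "fr",
    "mcl_s",
    "criterion_unmet",
]

TRIAL_LOG_COLUMNS = [
    "subject_id",
    "ion",
    "dose_cgy",
    "phase",
    "stage",
    "day",
    "attempt_index",
    "correct",
    "latency_s",
]


def scores_table(subjects: Iterable[Subject]) -> pd.DataFrame:
    """Long-format score table, one row per (subject, phase, stage)."""
    rows = []
    for subj in subjects:
        scored = score_subject(subj)
        for phase, stages in scored.items():
            for stage, ss in stages.items():
                rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "ion": subj.ion,
                        "dose_cgy": subj.dose_cgy,
                        "phase": phase,
                        "stage": stage,
                        "atrc": ss.atrc,
                        "fr": ss.fr,
                        "mcl_s": ss.mcl_s,
                        "criterion_unmet": int(ss.criterion_unmet),
                    }
                )
    return pd.DataFrame(rows, columns=SCORES_COLUMNS)


def write_scores_csv(subjects: Iterable[Subject], path) -> pd.DataFrame:
    table = scores_table(subjects)
    table.to_csv(path, index=False)
    return table


def read_scores_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in SCORES_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"scores CSV missing columns: {missing}")
    return table


def trial_log_table(subjects: Iterable[Subject]) -> pd.DataFrame:
    """One row per attempt, RFC-4180-friendly; empty latency for failures."""
    rows = []
    for subj in subjects:
        for phase, stages in (("prescreen", subj.prescreen), ("post", subj.post)):
            for stage, perf in stages.items():
                for day_no, day in ((1, perf.day1), (2, perf.day2)):
                    for idx, trial in enumerate(day, start=1):
                        rows.append(
                            {
                                "subject_id": subj.subject_id,
                                "ion": subj.ion,
                                "dose_cgy": subj.dose_cgy,
                                "phase": phase,
                                "stage": stage,
                                "day": day_no,
                                "attempt_index": idx,
                                "correct": int(trial.correct),
                                "latency_s": trial.latency_s,
                            }
                        )
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def write_trial_log_csv(subjects: Iterable[Subject], path) -> pd.DataFrame:
    table = trial_log_table(subjects)
    table.to_csv(path, index=False)
    return table


def _parse_trial_row(row: Mapping, line_no: int) -> dict:
    try:
        phase = str(row["phase"])
        if phase not in ("prescreen", "post"):
            raise ValueError(f"bad phase {phase!r}")
        day = int(row["day"])
        if day not in (1, 2):
            raise ValueError(f"bad day {day}")
        correct = int(row["correct"])
        if correct not in (0, 1):
            raise ValueError(f"bad correct flag {correct}")
        latency = row.get("latency_s")
        if latency is None or (isinstance(latency, float) and math.isnan(latency)) or latency == "":
            latency_s = None
        else:
            latency_s = float(latency)
        return {
            "subject_id": str(row["subject_id"]),
            "ion": str(row["ion"]),
            "dose_cgy": float(row["dose_cgy"]),
            "phase": phase,
            "stage": str(row["stage"]),
            "day": day,
            "attempt_index": int(row["attempt_index"]),
            "correct": bool(correct),
            "latency_s": latency_s,
        }
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"trial log line {line_no}: {exc}") from exc


def read_trial_log_csv(path) -> list[Subject]:
    """Rebuild subjects from a trial-log CSV, rejecting malformed rows."""
    table = pd.read_csv(path)
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial log missing columns: {missing}")
    parsed = [
        _parse_trial_row(row, line_no)
        for line_no, row in enumerate(table.to_dict("records"), start=2)
    ]
    subjects: dict[str, Subject] = {}
    # (subject, phase, stage) -> {day -> [TrialRecord]}
    staged: dict[tuple[str, str, str], dict[int, list[tuple[int, TrialRecord]]]] = {}
    for rec in parsed:
        sid = rec["subject_id"]
        if sid not in subjects:
            subjects[sid] = Subject(sid, rec["ion"], rec["dose_cgy"])
        key = (sid, rec["phase"], rec["stage"])
        trial = TrialRecord(rec["correct"], rec["latency_s"] if rec["correct"] else None)
        staged.setdefault(key, {}).setdefault(rec["day"], []).append(
            (rec["attempt_index"], trial)
        )
    for (sid, phase, stage), days in staged.items():
        day1 = [t for _, t in sorted(days.get(1, []))]
        day2 = [t for _, t in sorted(days.get(2, []))]
        perf = StagePerformance(stage=stage, day1=day1, day2=day2)
        getattr(subjects[sid], phase)[stage] = perf
    return list(subjects.values())
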