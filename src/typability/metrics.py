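"""Keystroke-log analytics: from raw typing trials to sentence typability.

Implements the outcome-variable pipeline: gross words-per-minute from key
timestamps, within-participant z-scoring of trial speeds, per-sentence mean
typability across participants, Levenshtein transcription accuracy, and the
participant exclusion filters (incomplete sessions, high error rate,
implausible inter-key intervals).

Typability of a sentence is the mean, across the participants who typed
it, of the participant's z-scored typing speed for that sentence: 0 means
typed at one's own average speed, +1 means one within-person standard
deviation faster.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from statistics import fmean
from typing import Iterable, Literal, Sequence

import edlib
import numpy as np

__all__ = [
    "KeyEvent",
    "TypingTrial",
    "ParticipantRecord",
    "SentenceTypability",
    "ExclusionReport",
    "gross_wpm",
    "levenshtein",
    "trial_accuracy",
    "participant_z_scores",
    "sentence_typability",
    "apply_exclusions",
    "read_keystroke_log",
    "write_keystroke_log",
    "write_sentence_csv",
]


@dataclass(frozen=True, slots=True)
class KeyEvent:
    """One key press/release with timestamps in seconds."""

    key_label: str
    press_time: float
    release_time: float

    def __post_init__(self):
        if self.press_time < 0 or self.release_time < self.press_time:
            raise ValueError(
                f"invalid key event times (press={self.press_time}, release={self.release_time})"
            )


@dataclass(slots=True)
class TypingTrial:
    """One participant x sentence typing episode."""

    participant_id: str
    item_id: str
    presented_text: str
    typed_text: str
    events: list[KeyEvent]

    def __post_init__(self):
        if not self.events:
            raise ValueError(f"trial ({self.participant_id}, {self.item_id}) has no key events")
        if not self.typed_text:
            raise ValueError(f"trial ({self.participant_id}, {self.item_id}) has empty typed text")
        presses = [e.press_time for e in self.events]
        if any(b < a for a, b in zip(presses, presses[1:])):
            raise ValueError(f"trial ({self.participant_id}, {self.item_id}) events not press-time ordered")

    @property
    def elapsed_seconds(self) -> float:
        """First key press to last key release."""
        return self.events[-1].release_time - self.events[0].press_time

    def inter_key_intervals(self) -> list[float]:
        presses = [e.press_time for e in self.events]
        return [b - a for a, b in zip(presses, presses[1:])]


@dataclass
class ParticipantRecord:
    """All trials of one participant."""

    participant_id: str
    trials: list[TypingTrial]

    def __post_init__(self):
        ids = [t.item_id for t in self.trials]
        if len(ids) != len(set(ids)):
            raise ValueError(f"participant {self.participant_id!r} has duplicate item_ids")


@dataclass(frozen=True)
class SentenceTypability:
    """Per-sentence outcome: mean z-scored speed and mean accuracy."""

    item_id: str
    mean_z: float
    n_participants: int
    mean_accuracy: float


def gross_wpm(trial: TypingTrial, denominator: Literal["typed", "presented"] = "typed") -> float:
    """Gross words per minute, unadjusted for errors.

    Words = characters (including spaces) / 5, over the interval from first
    key press to last key release.  The character count defaults to the
    typed string; ``denominator="presented"`` switches to the presented one.
    """
    elapsed = trial.elapsed_seconds
    if elapsed <= 0:
        raise ValueError(
            f"trial ({trial.participant_id}, {trial.item_id}): non-positive elapsed time {elapsed}"
        )
    text = trial.typed_text if denominator == "typed" else trial.presented_text
    return (len(text) / 5.0) / elapsed * 60.0


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if not a or not b:
        return len(a) or len(b)
    return edlib.align(a, b, task="distance")["editDistance"]


def trial_accuracy(presented: str, typed: str) -> float:
    """1 - (edit distance / presented length); not clamped below 0."""
    if not presented:
        raise ValueError("trial_accuracy requires a non-empty presented string")
    return 1.0 - levenshtein(typed, presented) / len(presented)


def participant_z_scores(
    record: ParticipantRecord,
    denominator: Literal["typed", "presented"] = "typed",
    ddof: int = 1,
) -> dict[str, float]:
    """Within-participant z-scores of trial speeds, ``z = (x - mu) / sigma``.

    mu and sigma are the participant's own mean and (by default sample,
    n-1) standard deviation over their trials; the resulting set has mean 0
    and SD 1 by construction.
    """
    if len(record.trials) < 2:
        raise ValueError(f"participant {record.participant_id!r}: need >= 2 trials to z-score")
    speeds = np.array([gross_wpm(t, denominator) for t in record.trials])
    sigma = speeds.std(ddof=ddof)
    if sigma <= 1e-9 * max(1.0, abs(float(speeds.mean()))):
        raise ValueError(f"participant {record.participant_id!r}: zero variance in trial speeds")
    z = (speeds - speeds.mean()) / sigma
    return {t.item_id: float(v) for t, v in zip(record.trials, z)}


def sentence_typability(
    all_records: Sequence[ParticipantRecord],
    denominator: Literal["typed", "presented"] = "typed",
    ddof: int = 1,
) -> list[SentenceTypability]:
    """Mean within-participant z-score (and mean accuracy) per sentence.

    Raises if any participant cannot be z-scored (fewer than two trials or
    zero speed variance); run :func:`apply_exclusions` first to drop such
    participants.
    """
    z_sums: dict[str, list[float]] = {}
    acc_sums: dict[str, list[float]] = {}
    for record in all_records:
        zs = participant_z_scores(record, denominator, ddof)
        for trial in record.trials:
            z_sums.setdefault(trial.item_id, []).append(zs[trial.item_id])
            acc_sums.setdefault(trial.item_id, []).append(
                trial_accuracy(trial.presented_text, trial.typed_text)
            )
    return [
        SentenceTypability(
            item_id=item,
            mean_z=fmean(z_sums[item]),
            n_participants=len(z_sums[item]),
            mean_accuracy=fmean(acc_sums[item]),
        )
        for item in sorted(z_sums)
    ]


@dataclass
class ExclusionReport:
    """Who was excluded and why."""

    excluded: dict[str, list[str]] = field(default_factory=dict)  # participant -> reasons

    def add(self, participant_id: str, reason: str) -> None:
        self.excluded.setdefault(participant_id, []).append(reason)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def apply_exclusions(
    records: Sequence[ParticipantRecord],
    required_trials: int = 15,
    max_error_rate: float = 0.25,
    max_iki: float = 50.0,
    denominator: Literal["typed", "presented"] = "typed",
) -> tuple[list[ParticipantRecord], ExclusionReport]:
    """Drop participants per the training-corpus exclusion criteria.

    Excluded: fewer than ``required_trials`` completed sentences; mean
    error rate (1 - accuracy, averaged over trials) of ``max_error_rate``
    or more; any inter-key interval (successive press-time difference)
    above ``max_iki`` seconds.  Degenerate speed variance (z undefined) is
    also excluded so the retained set is always z-scorable.
    """
    retained: list[ParticipantRecord] = []
    report = ExclusionReport()
    for record in records:
        reasons = []
        if len(record.trials) < required_trials:
            reasons.append(f"incomplete: {len(record.trials)} < {required_trials} trials")
        else:
            mean_error = fmean(
                1.0 - trial_accuracy(t.presented_text, t.typed_text) for t in record.trials
            )
            if mean_error >= max_error_rate:
                reasons.append(f"error rate {mean_error:.3f} >= {max_error_rate}")
            if any(iki > max_iki for t in record.trials for iki in t.inter_key_intervals()):
                reasons.append(f"inter-key interval above {max_iki} s")
            speeds = np.array([gross_wpm(t, denominator) for t in record.trials])
            if speeds.std(ddof=1) <= 1e-9 * max(1.0, abs(float(speeds.mean()))):
                reasons.append("zero variance in trial speeds")
        if reasons:
            for r in reasons:
                report.add(record.participant_id, r)
        else:
            retained.append(record)
    return retained, report


# --------------------------------------------------------------------------
# keystroke-log I/O
#
# Delimited tables in the public 136M Keystrokes Dataset dialect: one row
# per key event, with participant id, test section (sentence) id, the
# presented sentence, the final typed input, the key label and press/release
# timestamps in milliseconds.  A comma-separated dialect with the same
# columns is also supported.

LOG_COLUMNS = {
    "participant": "PARTICIPANT_ID",
    "section": "TEST_SECTION_ID",
    "presented": "SENTENCE",
    "typed": "USER_INPUT",
    "key": "LETTER",
    "press": "PRESS_TIME",
    "release": "RELEASE_TIME",
}


def read_keystroke_log(
    path: str | Path,
    dialect: Literal["tab", "csv"] = "tab",
    columns: dict[str, str] | None = None,
    time_unit: Literal["ms", "s"] = "ms",
) -> list[ParticipantRecord]:
    """Read a keystroke log into participant records.

    ``columns`` maps the roles in :data:`LOG_COLUMNS` to actual header
    names; timestamps are converted from milliseconds to seconds unless
    ``time_unit="s"``.
    """
    cols = dict(LOG_COLUMNS)
    cols.update(columns or {})
    scale = 1e-3 if time_unit == "ms" else 1.0
    delim = "\t" if dialect == "tab" else ","
    trials: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise ValueError(f"keystroke log {path} is empty")
        for role, colname in cols.items():
            if colname not in reader.fieldnames:
                raise ValueError(f"keystroke log {path} is missing column {colname!r} ({role})")
        for lineno, row in enumerate(reader, start=2):
            try:
                key = (row[cols["participant"]], row[cols["section"]])
                event = KeyEvent(
                    key_label=row[cols["key"]],
                    press_time=float(row[cols["press"]]) * scale,
                    release_time=float(row[cols["release"]]) * scale,
                )
                if key not in trials:
                    trials[key] = {
                        "presented": row[cols["presented"]],
                        "typed": row[cols["typed"]],
                        "events": [],
                    }
                    order.append(key)
                trials[key]["events"].append(event)
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
    if not trials:
        raise ValueError(f"keystroke log {path} contains no data rows")
    by_participant: dict[str, list[TypingTrial]] = {}
    for participant_id, section_id in order:
        data = trials[(participant_id, section_id)]
        by_participant.setdefault(participant_id, []).append(
            TypingTrial(
                participant_id=participant_id,
                item_id=section_id,
                presented_text=data["presented"],
                typed_text=data["typed"],
                events=data["events"],
            )
        )
    return [ParticipantRecord(pid, ts) for pid, ts in by_participant.items()]


def write_keystroke_log(
    records: Iterable[ParticipantRecord],
    path: str | Path,
    dialect: Literal["tab", "csv"] = "tab",
    time_unit: Literal["ms", "s"] = "ms",
) -> None:
    """Write participant records in the dialect read by :func:`read_keystroke_log`."""
    scale = 1e3 if time_unit == "ms" else 1.0
    delim = "\t" if dialect == "tab" else ","
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(LOG_COLUMNS[k] for k in ("participant", "section", "presented", "typed", "key", "press", "release"))
        for record in records:
            for trial in record.trials:
                for event in trial.events:
                    writer.writerow(
                        [
                            record.participant_id,
                            trial.item_id,
                            trial.presented_text,
                            trial.typed_text,
                            event.key_label,
                            f"{event.press_time * scale:.3f}",
                            f"{event.release_time * scale:.3f}",
                        ]
                    )


def write_sentence_csv(sentences: Iterable[SentenceTypability], path: str | Path) -> None:
    """Write per-sentence typability as CSV (item_id, mean_z, n, mean_accuracy)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["item_id", "mean_z", "n_participants", "mean_accuracy"])
        for s in sentences:
            writer.writerow([s.item_id, f"{s.mean_z:.6f}", s.n_participants, f"{s.mean_accuracy:.6f}"])
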