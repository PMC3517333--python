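"""Scoring for the 7-day recall instrument.

Each day the participant reports sleep hours plus, for three periods of the
day (morning / afternoon / evening), hours spent in each of five selectable
intensity classes. Time not accounted for by sleep or the reported entries is
filled as very-light activity (1.3 METs) — reading, television and similar
behaviors are not on the selection screen, so the residual of the 24-h budget
stands in for them.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from .compendium import INTENSITY_CLASSES, SELECTABLE_CLASSES
from .constants import DEFAULTS, StudyConstants
from .par24 import EEOutcome, score_from_avg_mets

PERIODS = ("morning", "afternoon", "evening")

_HOURS_EPS = 1e-9  # float-sum slack on the 24-h budget


class OverAllocationError(ValueError):
    """Raised when sleep plus reported activity exceeds 24 hours."""


@dataclass(frozen=True)
class RecallEntry:
    """Hours of one intensity class within one period of the day."""

    period: str
    intensity_class: str
    hours: float

    def __post_init__(self):
        if self.period not in PERIODS:
            raise ValueError(f"period must be one of {PERIODS}, got {self.period!r}")
        if self.intensity_class not in SELECTABLE_CLASSES:
            raise ValueError(
                f"intensity class must be one of {SELECTABLE_CLASSES}, "
                f"got {self.intensity_class!r}"
            )
        if self.hours < 0:
            raise ValueError(f"hours must be non-negative, got {self.hours}")


@dataclass(frozen=True)
class RecallDay:
    """One participant-day of recall input."""

    participant_id: str
    date: _dt.date
    sleep_hours: float
    entries: Tuple[RecallEntry, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))
        if not (0 <= self.sleep_hours <= 24):
            raise ValueError(
                f"sleep_hours must be in [0, 24], got {self.sleep_hours}"
            )
        total = self.sleep_hours + sum(e.hours for e in self.entries)
        if total > 24 + _HOURS_EPS:
            raise OverAllocationError(
                f"{self.participant_id} {self.date}: sleep + activity hours "
                f"= {total:.3f} exceed 24"
            )

    @property
    def unaccounted_hours(self) -> float:
        """Residual of the 24-h budget, scored as very-light time."""
        return max(0.0, 24.0 - self.sleep_hours - sum(e.hours for e in self.entries))


def average_mets_recall(day: RecallDay) -> float:
    """24-h average METs of a recall day.

    avg = [0.9*sleep + sum(class METs * hours) + 1.3*unaccounted] / 24.
    Entries sharing a class are summed; the period split is metadata only.
    """
    sleep_mets = INTENSITY_CLASSES["sleep"].mets
    fill_mets = INTENSITY_CLASSES["very_light"].mets
    met_hours = sleep_mets * day.sleep_hours
    for entry in day.entries:
        met_hours += INTENSITY_CLASSES[entry.intensity_class].mets * entry.hours
    met_hours += fill_mets * day.unaccounted_hours
    return met_hours / 24.0


def score_recall_day(day: RecallDay, bmr_kcal: float,
                     constants: StudyConstants = DEFAULTS) -> EEOutcome:
    """Score one recall day with the same kcal->MJ conversion as the diary.

    Both instruments share the conversion
    TEE = BMR * avgMET * 1.1/0.9 * 4.184e-3 so their outputs are comparable;
    see docs/methods.md for the rationale.
    """
    return score_from_avg_mets(average_mets_recall(day), bmr_kcal, constants)


def score_recall_week(days: Sequence[RecallDay], bmr_kcal: float,
                      constants: StudyConstants = DEFAULTS) -> EEOutcome:
    """Arithmetic mean of daily recall scores (1-7 days)."""
    if not days:
        raise ValueError("score_recall_week needs at least one day")
    daily = [score_recall_day(d, bmr_kcal, constants) for d in days]
    n = len(daily)
    avg = sum(d.avg_mets for d in daily) / n
    tee = sum(d.tee_mj for d in daily) / n
    bmr_mj = daily[0].bmr_mj
    from .par24 import aee_from_tee
    return EEOutcome(avg_mets=avg, tee_mj=tee,
                     aee_mj=aee_from_tee(tee, bmr_mj, constants),
                     pal=tee / bmr_mj, bmr_mj=bmr_mj)


def quiz_gate(answers: Sequence[Tuple[str, str]]) -> Tuple[bool, int]:
    """Evaluate the intensity-quiz pass rule: two correct answers in a row.

    ``answers`` is the submitted sequence of (asked class, answered class)
    pairs. Returns (passed, trials_used): ``passed`` is True at the first
    position where two consecutive answers are correct and ``trials_used`` is
    that position + 1; otherwise (False, len(answers)).
    """
    streak = 0
    for i, (asked, answered) in enumerate(answers):
        streak = streak + 1 if asked == answered else 0
        if streak >= 2:
            return True, i + 1
    return False, len(answers)
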