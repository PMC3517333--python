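"""Scoring for the 24-hour physical-activity record (96-slot diary).

A diary day is a grid of 96 activity codes, one per 15-minute slot from local
midnight to midnight. Scoring converts the grid into a time-weighted 24-h
average MET value and then into daily energy expenditure:

    TEE [MJ/d] = BMR [kcal/d] * avgMET * (1.1 / 0.9) * 4.184e-3
    AEE [MJ/d] = 0.9 * TEE - BMR [MJ/d]
    PAL        = TEE / BMR

where 1.1 anchors the MET scale at sitting rest (~10% above supine fasting
BMR) and the division by 0.9 adds ~10% diet-induced thermogenesis.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Sequence

from .compendium import Compendium, lookup_mets
from .constants import DEFAULTS, StudyConstants

SLOTS_PER_DAY = 96


@dataclass(frozen=True)
class DiaryDay:
    """One participant-day of diary input: exactly 96 slot activity codes.

    Slot ``i`` covers local time ``[15*i, 15*(i+1))`` minutes from midnight.
    Days with a different slot count (e.g. daylight-saving transitions) are
    rejected as malformed rather than silently scored.
    """

    participant_id: str
    date: _dt.date
    slots: tuple

    def __post_init__(self):
        object.__setattr__(self, "slots", tuple(self.slots))
        if len(self.slots) != SLOTS_PER_DAY:
            raise ValueError(
                f"diary day needs exactly {SLOTS_PER_DAY} slots, "
                f"got {len(self.slots)} for {self.participant_id} {self.date}"
            )


@dataclass(frozen=True)
class EEOutcome:
    """Scored energy-expenditure result for a day or a week of days."""

    avg_mets: float
    tee_mj: float
    aee_mj: float
    pal: float
    bmr_mj: float


def average_mets(day: DiaryDay, compendium: Compendium) -> float:
    """Time-weighted 24-h mean MET of a diary day (slots are equal length)."""
    total = 0.0
    for code in day.slots:
        total += lookup_mets(compendium, code)
    return total / SLOTS_PER_DAY


def aee_from_tee(tee_mj: float, bmr_mj: float,
                 constants: StudyConstants = DEFAULTS) -> float:
    """Activity energy expenditure: AEE = 0.9 * TEE - BMR (MJ/day)."""
    return constants.dit_factor * tee_mj - bmr_mj


def score_from_avg_mets(avg_mets: float, bmr_kcal: float,
                        constants: StudyConstants = DEFAULTS) -> EEOutcome:
    """Convert a 24-h average MET value and BMR (kcal/day) to an EEOutcome.

    No rounding is applied; report writers round for presentation only.
    """
    if bmr_kcal <= 0:
        raise ValueError(f"BMR must be positive (kcal/day), got {bmr_kcal}")
    if avg_mets <= 0:
        raise ValueError(f"average METs must be positive, got {avg_mets}")
    bmr_mj = bmr_kcal * constants.kcal_to_mj
    tee_mj = (bmr_kcal * avg_mets * constants.sitting_factor
              / constants.dit_factor * constants.kcal_to_mj)
    return EEOutcome(
        avg_mets=avg_mets,
        tee_mj=tee_mj,
        aee_mj=aee_from_tee(tee_mj, bmr_mj, constants),
        pal=tee_mj / bmr_mj,
        bmr_mj=bmr_mj,
    )


def score_day(day: DiaryDay, bmr_kcal: float, compendium: Compendium,
              constants: StudyConstants = DEFAULTS) -> EEOutcome:
    """Score one diary day into avg METs, TEE, AEE (MJ/day) and PAL."""
    return score_from_avg_mets(average_mets(day, compendium), bmr_kcal, constants)


def score_week(days: Sequence[DiaryDay], bmr_kcal: float,
               compendium: Compendium,
               constants: StudyConstants = DEFAULTS) -> EEOutcome:
    """Arithmetic mean of daily scores over 1-7 compliant days.

    PAL is recomputed from the mean TEE (identical to the mean of daily PALs
    here because BMR is constant within a participant).
    """
    if not days:
        raise ValueError("score_week needs at least one compliant day")
    daily = [score_day(d, bmr_kcal, compendium, constants) for d in days]
    n = len(daily)
    avg = sum(d.avg_mets for d in daily) / n
    tee = sum(d.tee_mj for d in daily) / n
    bmr_mj = daily[0].bmr_mj
    return EEOutcome(
        avg_mets=avg,
        tee_mj=tee,
        aee_mj=aee_from_tee(tee, bmr_mj, constants),
        pal=tee / bmr_mj,
        bmr_mj=bmr_mj,
    )
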