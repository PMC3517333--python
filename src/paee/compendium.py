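"""Activity catalog (MET compendium) and intensity-class tables.

The 24-h diary instrument records one activity behavior per 15-minute slot,
drawn from a catalog of behaviors split over four categories (work, commute,
leisure, sports); each behavior carries a MET intensity from the standard
compendium of physical activities. The 7-day recall instrument instead uses a
small fixed table of intensity classes with one scoring MET value each.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional

CATEGORIES = ("work", "commute", "leisure", "sports")


class UnknownActivityError(KeyError):
    """Raised when a diary slot references a code absent from the catalog."""


@dataclass(frozen=True)
class Activity:
    """One behavior in the catalog.

    Parameters
    ----------
    code : str
        Short stable identifier used in diary files.
    label : str
        Human-readable description.
    category : str
        One of ``work``, ``commute``, ``leisure``, ``sports``.
    mets : float
        Intensity as a multiple of resting metabolic rate, 0 < mets <= 20.
    """

    code: str
    label: str
    category: str
    mets: float

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category {self.category!r} not in {CATEGORIES}"
            )
        if not (0 < self.mets <= 20):
            raise ValueError(f"mets must be in (0, 20], got {self.mets}")


@dataclass(frozen=True)
class Compendium:
    """Immutable code -> Activity lookup table."""

    activities: Dict[str, Activity]
    version: str = "default"

    def __len__(self) -> int:
        return len(self.activities)

    def __contains__(self, code: str) -> bool:
        return code in self.activities

    def __iter__(self):
        return iter(self.activities.values())

    def lookup(self, code: str) -> Activity:
        try:
            return self.activities[code]
        except KeyError:
            raise UnknownActivityError(
                f"unknown activity code {code!r}"
            ) from None

    @classmethod
    def from_activities(cls, activities: Iterable[Activity],
                        version: str = "custom") -> "Compendium":
        table: Dict[str, Activity] = {}
        for act in activities:
            if act.code in table:
                raise ValueError(f"duplicate activity code {act.code!r}")
            table[act.code] = act
        return cls(activities=table, version=version)

    @classmethod
    def from_csv(cls, path: str | Path, version: Optional[str] = None) -> "Compendium":
        """Load a catalog from a UTF-8 CSV with header code,label,category,mets."""
        path = Path(path)
        acts = []
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"code", "label", "category", "mets"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValueError(
                    f"{path}: compendium CSV must have columns {sorted(required)}"
                )
            for row in reader:
                acts.append(Activity(code=row["code"].strip(),
                                     label=row["label"].strip(),
                                     category=row["category"].strip(),
                                     mets=float(row["mets"])))
        return cls.from_activities(acts, version=version or path.name)

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["code", "label", "category", "mets"])
            for act in sorted(self.activities.values(), key=lambda a: a.code):
                writer.writerow([act.code, act.label, act.category, act.mets])


def lookup_mets(compendium: Compendium, code: str) -> float:
    """MET intensity bound to ``code``; raises UnknownActivityError otherwise."""
    return compendium.lookup(code).mets


# ---------------------------------------------------------------------------
# Default catalog. Intensities follow the standard compendium of physical
# activities for behaviors common to Japanese adult time-use surveys. The
# original instrument's per-activity list is not published; this table is a
# documented stand-in and can be replaced via Compendium.from_csv.
# ---------------------------------------------------------------------------

_DEFAULT_TABLE = [
    # code, label, category, METs
    # -- work-related --
    ("office_work", "desk work in an office", "work", 1.5),
    ("computer_work", "computer work, typing", "work", 1.3),
    ("telephone_work", "telephone work, sitting", "work", 1.3),
    ("meeting", "meeting, sitting", "work", 1.5),
    ("standing_work", "standing work, light", "work", 2.3),
    ("teaching", "teaching, standing", "work", 2.5),
    ("retail_sales", "retail sales, standing/walking", "work", 3.0),
    ("light_assembly", "light assembly-line work", "work", 2.5),
    ("cooking_work", "cooking, occupational", "work", 3.3),
    ("cleaning_work", "cleaning, occupational", "work", 3.3),
    ("nursing_care", "nursing or caregiving work", "work", 4.0),
    ("farming_light", "farming, light effort", "work", 3.8),
    ("farming_heavy", "farming, vigorous effort", "work", 5.8),
    ("construction", "construction, general", "work", 4.0),
    ("carpentry", "carpentry, general", "work", 4.3),
    ("heavy_lifting", "loading and carrying heavy loads", "work", 6.5),
    # -- way to work / transport --
    ("walking_commute", "walking to work or errands", "commute", 3.5),
    ("brisk_walk_commute", "brisk walking to work", "commute", 4.3),
    ("cycling_commute", "bicycling to work", "commute", 6.8),
    ("driving_car", "driving a car", "commute", 2.5),
    ("motorbike", "riding a motor scooter", "commute", 2.8),
    ("bus_standing", "standing in a bus or train", "commute", 2.0),
    ("train_sitting", "riding seated in a train", "commute", 1.3),
    ("waiting_transport", "waiting for transport, standing", "commute", 1.3),
    # -- leisure-time --
    ("sleep", "sleeping", "leisure", 0.9),
    ("napping", "napping during the day", "leisure", 0.9),
    ("lying_awake", "lying quietly, awake", "leisure", 1.0),
    ("sitting_quietly", "sitting quietly", "leisure", 1.1),
    ("watching_tv", "watching television, seated", "leisure", 1.0),
    ("reading", "reading, seated", "leisure", 1.3),
    ("internet_use", "internet or smartphone use, seated", "leisure", 1.3),
    ("phone_conversation", "telephone conversation, seated", "leisure", 1.3),
    ("conversation", "conversation while seated", "leisure", 1.5),
    ("eating", "eating a meal, seated", "leisure", 1.5),
    ("bathing", "bathing, washing", "leisure", 1.5),
    ("board_games", "board or card games", "leisure", 1.5),
    ("hobby_crafts", "handicrafts, light hobbies", "leisure", 1.8),
    ("dishwashing", "washing dishes, standing", "leisure", 1.8),
    ("playing_music", "playing a musical instrument", "leisure", 2.0),
    ("personal_care", "grooming, dressing", "leisure", 2.0),
    ("cooking_home", "home cooking, meal preparation", "leisure", 2.0),
    ("laundry", "doing laundry", "leisure", 2.0),
    ("shopping", "shopping with a cart or basket", "leisure", 2.3),
    ("child_care_light", "child care, sitting/kneeling", "leisure", 2.5),
    ("pet_care", "feeding and grooming pets", "leisure", 2.8),
    ("house_cleaning", "house cleaning, general", "leisure", 3.3),
    ("vacuuming", "vacuuming", "leisure", 3.3),
    ("walking_dog", "walking the dog", "leisure", 3.0),
    ("child_care_active", "playing actively with children", "leisure", 3.5),
    ("gardening", "gardening, general", "leisure", 3.8),
    # -- sports --
    ("stretching", "mild stretching", "sports", 2.3),
    ("yoga", "yoga, hatha", "sports", 2.5),
    ("gateball", "gateball / croquet", "sports", 3.3),
    ("walking_exercise", "walking for exercise, moderate pace", "sports", 3.5),
    ("strength_training", "resistance training, light-moderate", "sports", 3.5),
    ("table_tennis", "table tennis", "sports", 4.0),
    ("volleyball", "volleyball, non-competitive", "sports", 4.0),
    ("brisk_walking", "brisk walking for exercise", "sports", 4.3),
    ("dancing", "dancing, general", "sports", 4.5),
    ("golf", "golf, walking the course", "sports", 4.8),
    ("baseball", "baseball / softball", "sports", 5.0),
    ("cycling_leisure", "bicycling for leisure", "sports", 5.8),
    ("hiking", "hiking, cross country", "sports", 6.0),
    ("swimming", "swimming, leisurely", "sports", 6.0),
    ("basketball", "basketball, non-game", "sports", 6.5),
    ("jogging", "jogging, general", "sports", 7.0),
    ("soccer", "soccer, casual", "sports", 7.0),
    ("tennis", "tennis, general", "sports", 7.3),
    ("aerobics", "aerobics, general", "sports", 7.3),
    ("running", "running, ~6 mph", "sports", 9.8),
]


def default_compendium() -> Compendium:
    """The shipped catalog (>= 66 behaviors over the four categories)."""
    return Compendium.from_activities(
        (Activity(code=c, label=l, category=cat, mets=m)
         for c, l, cat, m in _DEFAULT_TABLE),
        version="default-1",
    )


# ---------------------------------------------------------------------------
# Intensity classes (recall instrument)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntensityClass:
    """A recall intensity class: a name, its single scoring MET value, and,
    where defined, the descriptive MET range used to classify activities."""

    name: str
    mets: float
    met_range_low: Optional[float] = None
    met_range_high: Optional[float] = None  # inclusive printed upper bound


#: Scoring table: sleep and the very-light filler have fixed MET values but no
#: descriptive range; the five selectable classes carry the printed ranges.
INTENSITY_CLASSES: Dict[str, IntensityClass] = {
    c.name: c
    for c in (
        IntensityClass("sleep", 0.9),
        IntensityClass("very_light", 1.3),
        IntensityClass("light", 2.2, 1.5, 2.9),
        IntensityClass("moderate", 3.5, 3.0, 3.9),
        IntensityClass("moderate_high", 4.5, 4.0, 5.9),
        IntensityClass("high", 7.0, 6.0, 7.9),
        IntensityClass("very_high", 10.0, 8.0, None),
    )
}

#: Classes a participant can actually select on the recall screen.
SELECTABLE_CLASSES = ("light", "moderate", "moderate_high", "high", "very_high")

# Half-open classification bins [low, next_low) extending the printed closed
# ranges so the mapping is total over positive METs (the printed ranges leave
# e.g. 2.9-3.0 undefined; ties go to the lower class).
_CLASS_BINS = (
    ("light", 1.5, 3.0),
    ("moderate", 3.0, 4.0),
    ("moderate_high", 4.0, 6.0),
    ("high", 6.0, 8.0),
    ("very_high", 8.0, float("inf")),
)


def class_for_mets(mets: float, asleep: bool = False) -> IntensityClass:
    """Map a MET value to its intensity class.

    Values below 1.5 METs fall in the sub-light region the recall screen
    does not offer; they map to ``sleep`` when the caller flags the time as
    sleep and to ``very_light`` otherwise.
    """
    if mets <= 0:
        raise ValueError(f"mets must be positive, got {mets}")
    if mets < 1.5:
        return INTENSITY_CLASSES["sleep" if asleep else "very_light"]
    for name, low, high in _CLASS_BINS:
        if low <= mets < high:
            return INTENSITY_CLASSES[name]
    raise AssertionError("unreachable: bins cover [1.5, inf)")
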