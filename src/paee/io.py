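"""CSV readers/writers and the YAML run configuration.

All files are UTF-8, comma-delimited, header-required; dates are ISO-8601.
Schemas:

- diary:    participant_id,date,slot_index,activity_code (one row per slot,
            slot_index 0-95; a day missing any slot is non-compliant)
- recall:   participant_id,date,period,intensity_class,hours; the row with
            period='sleep' and intensity_class='sleep' carries that day's
            sleep hours
- isotopes: participant_id,time_days,delta_2h_permil,delta_18o_permil
            (the time_days == 0 row is the pre-dose baseline)
- doses:    participant_id,mass_2h2o_g,atom_pct_2h,mass_h218o_g,atom_pct_18o
- gas:      participant_id,minute,vo2_ml_min,vco2_ml_min
- bmr:      participant_id plus bmr_kcal_day or bmr_mj_day
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from .calorimetry import GasExchangeSeries
from .constants import DEFAULTS, StudyConstants
from .dlw import DosingRecord, IsotopeSample
from .par24 import SLOTS_PER_DAY, DiaryDay
from .recall7 import RecallDay, RecallEntry
from .simulate import StudyData


class SchemaError(ValueError):
    """A file does not match its documented schema."""


def _read_csv(path, required: set) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


def _parse_date(value) -> _dt.date:
    return _dt.date.fromisoformat(str(value))


# -- diary -------------------------------------------------------------------

def read_diary_csv(path) -> Tuple[Dict[str, List[DiaryDay]],
                                  List[Tuple[str, _dt.date, str]]]:
    """Diary days keyed by participant, plus a list of non-compliant
    (participant, date, reason) days that could not be scored."""
    df = _read_csv(path, {"participant_id", "date", "slot_index",
                          "activity_code"})
    days: Dict[str, List[DiaryDay]] = {}
    rejected: List[Tuple[str, _dt.date, str]] = []
    for (pid, date), grp in df.groupby(["participant_id", "date"], sort=True):
        pid = str(pid)
        date = _parse_date(date)
        slots = dict(zip(grp["slot_index"].astype(int),
                         grp["activity_code"].astype(str)))
        missing = [i for i in range(SLOTS_PER_DAY) if i not in slots]
        if missing or len(grp) != SLOTS_PER_DAY:
            reason = (f"missing slots {missing[:5]}..." if missing
                      else "duplicate slot rows")
            rejected.append((pid, date, reason))
            continue
        days.setdefault(pid, []).append(DiaryDay(
            participant_id=pid, date=date,
            slots=tuple(slots[i] for i in range(SLOTS_PER_DAY))))
    for lst in days.values():
        lst.sort(key=lambda d: d.date)
    return days, rejected


def write_diary_csv(days: Dict[str, List[DiaryDay]], path) -> None:
    rows = []
    for pid in sorted(days):
        for day in days[pid]:
            for i, code in enumerate(day.slots):
                rows.append((pid, day.date.isoformat(), i, code))
    pd.DataFrame(rows, columns=["participant_id", "date", "slot_index",
                                "activity_code"]).to_csv(path, index=False)


# -- recall ------------------------------------------------------------------

def read_recall_csv(path) -> Dict[str, List[RecallDay]]:
    df = _read_csv(path, {"participant_id", "date", "period",
                          "intensity_class", "hours"})
    days: Dict[str, List[RecallDay]] = {}
    for (pid, date), grp in df.groupby(["participant_id", "date"], sort=True):
        pid = str(pid)
        date = _parse_date(date)
        sleep_rows = grp[grp["period"] == "sleep"]
        if len(sleep_rows) != 1:
            raise SchemaError(
                f"{pid} {date}: expected exactly one sleep row, "
                f"got {len(sleep_rows)}"
            )
        entries = [
            RecallEntry(period=str(r.period),
                        intensity_class=str(r.intensity_class),
                        hours=float(r.hours))
            for r in grp[grp["period"] != "sleep"].itertuples()
        ]
        days.setdefault(pid, []).append(RecallDay(
            participant_id=pid, date=date,
            sleep_hours=float(sleep_rows["hours"].iloc[0]),
            entries=tuple(entries)))
    for lst in days.values():
        lst.sort(key=lambda d: d.date)
    return days


def write_recall_csv(days: Dict[str, List[RecallDay]], path) -> None:
    rows = []
    for pid in sorted(days):
        for day in days[pid]:
            date = day.date.isoformat()
            rows.append((pid, date, "sleep", "sleep", day.sleep_hours))
            for e in day.entries:
                rows.append((pid, date, e.period, e.intensity_class, e.hours))
    pd.DataFrame(rows, columns=["participant_id", "date", "period",
                                "intensity_class", "hours"]).to_csv(
        path, index=False)


# -- isotopes / doses --------------------------------------------------------

def read_isotope_csv(path) -> Dict[str, List[IsotopeSample]]:
    df = _read_csv(path, {"participant_id", "time_days", "delta_2h_permil",
                          "delta_18o_permil"})
    out: Dict[str, List[IsotopeSample]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.participant_id), []).append(IsotopeSample(
            time_days=float(r.time_days),
            delta_2h_permil=float(r.delta_2h_permil),
            delta_18o_permil=float(r.delta_18o_permil)))
    for lst in out.values():
        lst.sort(key=lambda s: s.time_days)
    return out


def write_isotope_csv(samples: Dict[str, List[IsotopeSample]], path) -> None:
    rows = [(pid, s.time_days, s.delta_2h_permil, s.delta_18o_permil)
            for pid in sorted(samples) for s in samples[pid]]
    pd.DataFrame(rows, columns=["participant_id", "time_days",
                                "delta_2h_permil", "delta_18o_permil"]
                 ).to_csv(path, index=False)


def read_dose_csv(path) -> Dict[str, DosingRecord]:
    df = _read_csv(path, {"participant_id", "mass_2h2o_g", "atom_pct_2h",
                          "mass_h218o_g", "atom_pct_18o"})
    return {
        str(r.participant_id): DosingRecord(
            participant_id=str(r.participant_id),
            mass_2h2o_g=float(r.mass_2h2o_g),
            atom_pct_2h=float(r.atom_pct_2h),
            mass_h218o_g=float(r.mass_h218o_g),
            atom_pct_18o=float(r.atom_pct_18o))
        for r in df.itertuples()
    }


def write_dose_csv(doses: Dict[str, DosingRecord], path) -> None:
    rows = [(pid, d.mass_2h2o_g, d.atom_pct_2h, d.mass_h218o_g, d.atom_pct_18o)
            for pid, d in sorted(doses.items())]
    pd.DataFrame(rows, columns=["participant_id", "mass_2h2o_g", "atom_pct_2h",
                                "mass_h218o_g", "atom_pct_18o"]
                 ).to_csv(path, index=False)


# -- gas / BMR ---------------------------------------------------------------

def read_gas_csv(path) -> Dict[str, GasExchangeSeries]:
    df = _read_csv(path, {"participant_id", "minute", "vo2_ml_min",
                          "vco2_ml_min"})
    out = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("minute")
        out[str(pid)] = GasExchangeSeries(
            participant_id=str(pid),
            minutes=tuple(grp["minute"].astype(int)),
            vo2_ml_min=tuple(grp["vo2_ml_min"].astype(float)),
            vco2_ml_min=tuple(grp["vco2_ml_min"].astype(float)))
    return out


def write_gas_csv(series: Dict[str, GasExchangeSeries], path) -> None:
    rows = [(pid, m, v, c)
            for pid, s in sorted(series.items())
            for m, v, c in zip(s.minutes, s.vo2_ml_min, s.vco2_ml_min)]
    pd.DataFrame(rows, columns=["participant_id", "minute", "vo2_ml_min",
                                "vco2_ml_min"]).to_csv(path, index=False)


def read_bmr_csv(path) -> Dict[str, float]:
    """BMR per participant, returned in kcal/day whichever unit is on file."""
    df = _read_csv(path, {"participant_id"})
    if "bmr_kcal_day" in df.columns:
        return {str(r.participant_id): float(r.bmr_kcal_day)
                for r in df.itertuples()}
    if "bmr_mj_day" in df.columns:
        return {str(r.participant_id): float(r.bmr_mj_day) / DEFAULTS.kcal_to_mj
                for r in df.itertuples()}
    raise SchemaError(f"{path}: need a bmr_kcal_day or bmr_mj_day column")


def write_bmr_csv(bmr_kcal: Dict[str, float], path,
                  constants: StudyConstants = DEFAULTS) -> None:
    rows = [(pid, kcal, kcal * constants.kcal_to_mj)
            for pid, kcal in sorted(bmr_kcal.items())]
    pd.DataFrame(rows, columns=["participant_id", "bmr_kcal_day",
                                "bmr_mj_day"]).to_csv(path, index=False)


# -- simulated-study bundle --------------------------------------------------

def write_study_csvs(data: StudyData, outdir) -> Dict[str, Path]:
    """Write a simulated study to diary/recall/iso/dose/gas/truth CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / f"{name}.csv"
             for name in ("diary", "recall", "iso", "dose", "gas", "truth",
                          "assignment")}
    write_diary_csv(data.diary_days, paths["diary"])
    write_recall_csv(data.recall_days, paths["recall"])
    write_isotope_csv(data.isotope_samples, paths["iso"])
    write_dose_csv(data.doses, paths["dose"])
    write_gas_csv(data.gas_series, paths["gas"])
    truth_rows = [
        (pid, t["tee_mj_week1"], t["tee_mj_week2"], t["bmr_mj_day"],
         t["true_pal"], t["nd_no_ratio"])
        for pid, t in sorted(data.truth.items())
    ]
    pd.DataFrame(truth_rows, columns=[
        "participant_id", "tee_mj_week1", "tee_mj_week2", "bmr_mj_day",
        "true_pal", "nd_no_ratio"]).to_csv(paths["truth"], index=False)
    assign_rows = [(pid, w1, w2)
                   for pid, (w1, w2) in sorted(data.assignment.items())]
    pd.DataFrame(assign_rows, columns=[
        "participant_id", "week1_instrument", "week2_instrument"]
    ).to_csv(paths["assignment"], index=False)
    return paths


# -- run configuration -------------------------------------------------------

@dataclass
class RunConfig:
    """Paths and constants for a full study run.

    Either the five input paths are set, or ``simulate_n`` asks the pipeline
    to generate the inputs itself. ``constants`` starts from the protocol
    defaults; overrides arrive via the YAML ``constants:`` block and are
    echoed in the report.
    """

    diary: Optional[str] = None
    recall: Optional[str] = None
    isotopes: Optional[str] = None
    doses: Optional[str] = None
    gas: Optional[str] = None
    bmr: Optional[str] = None
    outdir: str = "study_out"
    seed: int = 0
    simulate_n: Optional[int] = None
    constants: StudyConstants = field(default_factory=lambda: DEFAULTS)
    overridden: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    overrides = raw.pop("constants", {}) or {}
    constants = DEFAULTS.override(**overrides)
    known = {"diary", "recall", "isotopes", "doses", "gas", "bmr",
             "outdir", "seed", "simulate_n"}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(constants=constants, overridden=dict(overrides), **raw)
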