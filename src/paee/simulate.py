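"""Synthetic crossover cohort with a ground-truth layer.

The simulator is truth-first: it draws each participant's physiology, builds
a per-day 96-slot activity schedule whose implied physical activity level
matches the participant's true PAL, and then derives every measured quantity
from that truth — diary reports (with slot misclassification), recall reports
(with class quantization, hour perturbation and an optional gross
overestimator), isotope enrichment series (by inverting the DLW chain, with
analytic noise on the delta values) and basal gas-exchange series. Parameter
recovery is therefore well defined: every estimator can be checked against
the generating values.

Default physiology reproduces the reference cohort: 20 adults (10 men, 10
women, ages 25-61), male BMR ~ N(6.50, 0.89) MJ/day truncated to 4.77-8.00,
dilution-space ratio N_d/N_O ~ N(1.027, 0.007) truncated to 1.011-1.043, and
analytic delta SDs of 0.7 permil (2H) and 0.05 permil (18O).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .calorimetry import GasExchangeSeries
from .compendium import (Compendium, SELECTABLE_CLASSES, class_for_mets,
                         default_compendium, lookup_mets)
from .constants import DEFAULTS, WATER_MOLAR_MASS_G, StudyConstants
from .dlw import (DosingRecord, IsotopeSample, atom_fraction_to_delta,
                  delta_to_atom_fraction, tracer_moles)
from .par24 import SLOTS_PER_DAY, DiaryDay
from .recall7 import PERIODS, RecallDay, RecallEntry

INSTRUMENTS = ("par24", "recall7")
OCCUPATIONS = ("fulltime", "parttime", "selfemployed", "homemaker")
#: Occupation mix of the reference cohort (50/10/20/20 %).
OCCUPATION_PROBS = (0.5, 0.1, 0.2, 0.2)

START_DATE = _dt.date(2012, 1, 2)  # day 0 of the 14-day observation

#: Pre-dose body-water enrichment (delta-permil vs VSMOW).
BASELINE_DELTA_2H = -55.0
BASELINE_DELTA_18O = -7.0

#: Protocol dose sizes, grams of labeled water per kg predicted TBW.
DOSE_2H2O_G_PER_KG_TBW = 0.12
DOSE_H218O_G_PER_KG_TBW = 2.5

#: Nominal urine sampling days: baseline plus duplicates on days 1, 8, 15.
SAMPLING_DAYS = (1.0, 8.0, 15.0)

_SLEEP_CODES = frozenset({"sleep", "napping"})
_SITTING = "sitting_quietly"

#: Sex-stratified physiology: (mean, sd, low, high) truncated normals.
PHYSIOLOGY = {
    "male": {
        "age": (45.2, 12.3, 26.0, 61.0),
        "weight_kg": (79.2, 13.9, 57.5, 108.5),
        "height_cm": (172.6, 7.3, 161.9, 185.4),
        "bmr_mj_day": (6.50, 0.89, 4.77, 8.00),
        "true_pal": (1.90, 0.12, 1.68, 2.09),
        "tbw_fraction": (0.60, 0.02, 0.52, 0.68),
    },
    "female": {
        "age": (40.0, 9.1, 25.0, 51.0),
        "weight_kg": (54.0, 3.6, 48.7, 58.0),
        "height_cm": (159.0, 8.5, 141.8, 171.0),
        "bmr_mj_day": (4.87, 0.57, 4.40, 6.24),
        "true_pal": (1.76, 0.22, 1.42, 2.14),
        "tbw_fraction": (0.50, 0.02, 0.42, 0.58),
    },
}
ND_NO = (1.027, 0.007, 1.011, 1.043)
K_D = (0.10, 0.012, 0.07, 0.14)  # 2H elimination, 1/day (water turnover)


@dataclass(frozen=True)
class SimParticipant:
    id: str
    sex: str
    age: float
    weight_kg: float
    height_cm: float
    bmr_mj_day: float
    tbw_mol: float
    true_pal: float
    nd_no_ratio: float
    k_d_perday: float
    occupation: str


@dataclass(frozen=True)
class NoiseConfig:
    """Reporting and analytic error magnitudes.

    The delta SDs are the documented analytic precisions; the reporting-noise
    magnitudes are free simulator parameters (they are deliberately not fitted
    to any observed correlation). ``gross_overestimator_prob`` is the chance a
    participant reports every waking hour as moderate activity on the recall
    instrument, mimicking the constant-class entry error seen in practice.
    ``female_bias`` optionally inflates women's reported activity hours by the
    given fraction; it is off by default.
    """

    sd_delta2h_permil: float = 0.7
    sd_delta18o_permil: float = 0.05
    diary_misclass_prob: float = 0.05
    recall_hours_cv: float = 0.15
    gross_overestimator_prob: float = 0.05
    female_bias: float = 0.0

    def __post_init__(self):
        for p in (self.diary_misclass_prob, self.gross_overestimator_prob):
            if not (0 <= p <= 1):
                raise ValueError(f"probability {p} outside [0, 1]")
        for s in (self.sd_delta2h_permil, self.sd_delta18o_permil,
                  self.recall_hours_cv):
            if s < 0:
                raise ValueError(f"noise SD/CV must be >= 0, got {s}")

    @classmethod
    def zero(cls) -> "NoiseConfig":
        """All error channels off (the noiseless oracle configuration)."""
        return cls(sd_delta2h_permil=0.0, sd_delta18o_permil=0.0,
                   diary_misclass_prob=0.0, recall_hours_cv=0.0,
                   gross_overestimator_prob=0.0, female_bias=0.0)


def _trunc_normal(rng: np.random.Generator, mean, sd, lo, hi, size):
    """Truncated-normal draws by rejection (vectorized)."""
    out = np.empty(size, dtype=float)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size - filled)
        ok = draw[(draw >= lo) & (draw <= hi)]
        out[filled:filled + ok.size] = ok
        filled += ok.size
    return out


def generate_cohort(n: int, seed: int
                    ) -> Tuple[List[SimParticipant], Dict[str, Tuple[str, str]]]:
    """Sample ``n`` participants and a balanced crossover assignment.

    Sexes alternate so an even ``n`` splits 50/50; half the cohort uses the
    diary in week 1 and the recall in week 2, the other half the reverse.
    Reproducible bit-for-bit under a fixed seed.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 participants, got {n}")
    rng = np.random.default_rng(seed)
    participants: List[SimParticipant] = []
    sexes = ["male" if i % 2 == 0 else "female" for i in range(n)]
    for sex in ("male", "female"):
        idx = [i for i, s in enumerate(sexes) if s == sex]
        if not idx:
            continue
        phys = PHYSIOLOGY[sex]
        cols = {k: _trunc_normal(rng, *phys[k], size=len(idx))
                for k in ("age", "weight_kg", "height_cm",
                          "bmr_mj_day", "true_pal", "tbw_fraction")}
        ratios = _trunc_normal(rng, *ND_NO, size=len(idx))
        kds = _trunc_normal(rng, *K_D, size=len(idx))
        occ = rng.choice(OCCUPATIONS, size=len(idx), p=OCCUPATION_PROBS)
        for j, i in enumerate(idx):
            tbw_kg = cols["weight_kg"][j] * cols["tbw_fraction"][j]
            participants.append(SimParticipant(
                id=f"P{i + 1:03d}",
                sex=sex,
                age=float(cols["age"][j]),
                weight_kg=float(cols["weight_kg"][j]),
                height_cm=float(cols["height_cm"][j]),
                bmr_mj_day=float(cols["bmr_mj_day"][j]),
                tbw_mol=float(tbw_kg * 1000.0 / WATER_MOLAR_MASS_G),
                true_pal=float(cols["true_pal"][j]),
                nd_no_ratio=float(ratios[j]),
                k_d_perday=float(kds[j]),
                occupation=str(occ[j]),
            ))
    participants.sort(key=lambda p: p.id)

    order = rng.permutation(n)
    assignment: Dict[str, Tuple[str, str]] = {}
    half = n // 2 + (n % 2)
    for rank, i in enumerate(order):
        pid = participants[i].id
        if rank < half:
            assignment[pid] = ("par24", "recall7")
        else:
            assignment[pid] = ("recall7", "par24")
    return participants, assignment


# ---------------------------------------------------------------------------
# truth schedules
# ---------------------------------------------------------------------------

#: Occupation flavor: a few characteristic daytime behaviors, plus the main
#: activity used to push the day's average METs up to the participant's PAL.
_OCCUPATION_POOL = {
    "fulltime": ("walking_commute", ("office_work", "meeting", "standing_work",
                                     "computer_work", "eating")),
    "parttime": ("retail_sales", ("standing_work", "shopping", "cooking_home",
                                  "eating")),
    "selfemployed": ("farming_light", ("driving_car", "office_work",
                                       "standing_work", "eating")),
    "homemaker": ("house_cleaning", ("cooking_home", "child_care_light",
                                     "shopping", "eating")),
}


def implied_pal(grid: Sequence[str], compendium: Compendium,
                constants: StudyConstants = DEFAULTS) -> float:
    """PAL implied by a truth grid under the diary conversion:
    avgMET x sitting_factor / dit_factor."""
    avg = sum(lookup_mets(compendium, c) for c in grid) / len(grid)
    return avg * constants.sitting_factor / constants.dit_factor


def generate_true_schedule(p: SimParticipant, days: int, seed: int,
                           compendium: Optional[Compendium] = None,
                           constants: StudyConstants = DEFAULTS
                           ) -> List[Tuple[str, ...]]:
    """Per-day 96-slot activity-code grids matching the participant's PAL.

    Each day: a sleep block (7.5-8.5 h), occupation-flavored daytime slots,
    and a calibrated number of slots of the occupation's main activity so the
    day's implied PAL equals ``p.true_pal`` within 1% (a final single-slot
    substitution trims the residual). Slot placement is shuffled per day.
    """
    comp = compendium or default_compendium()
    rng = np.random.default_rng(seed)
    sitting_met = lookup_mets(comp, _SITTING)
    sleep_met = lookup_mets(comp, "sleep")
    main_code, flavor = _OCCUPATION_POOL[p.occupation]
    main_step = lookup_mets(comp, main_code) - sitting_met
    # substitution menu for the residual trim: one sitting slot -> code
    menu = sorted(
        ((lookup_mets(comp, a.code) - sitting_met, a.code)
         for a in comp if a.mets >= sitting_met and a.code not in _SLEEP_CODES),
        key=lambda t: t[0],
    )

    target_avg = p.true_pal * constants.dit_factor / constants.sitting_factor
    schedule: List[Tuple[str, ...]] = []
    for _ in range(days):
        sleep_slots = int(rng.integers(30, 35))
        codes = ["sleep"] * sleep_slots + [_SITTING] * (SLOTS_PER_DAY - sleep_slots)
        deficit = (SLOTS_PER_DAY * target_avg
                   - sleep_met * sleep_slots
                   - sitting_met * (SLOTS_PER_DAY - sleep_slots))
        cursor = sleep_slots  # next sitting slot to overwrite
        for code in flavor:
            step = lookup_mets(comp, code) - sitting_met
            if deficit - step >= 0 and cursor < SLOTS_PER_DAY - 1:
                codes[cursor] = code
                cursor += 1
                deficit -= step
        if main_step > 0:
            n_main = min(int(deficit // main_step),
                         SLOTS_PER_DAY - 1 - cursor)
            for _ in range(n_main):
                codes[cursor] = main_code
                cursor += 1
            deficit -= n_main * main_step
        if cursor < SLOTS_PER_DAY and deficit > 0:
            best = min(menu, key=lambda t: abs(t[0] - deficit))
            if abs(best[0] - deficit) < deficit:
                codes[cursor] = best[1]
        # shuffle waking slots; keep the sleep block contiguous at the start
        waking = codes[sleep_slots:]
        rng.shuffle(waking)
        schedule.append(tuple(codes[:sleep_slots] + waking))
    return schedule


# ---------------------------------------------------------------------------
# instrument reports
# ---------------------------------------------------------------------------

def _period_of_slot(i: int) -> str:
    if i < 48:
        return "morning"
    if i < 72:
        return "afternoon"
    return "evening"


def render_reports(grids: Sequence[Sequence[str]], p: SimParticipant,
                   noise: NoiseConfig, seed: int,
                   compendium: Optional[Compendium] = None
                   ) -> Tuple[List[DiaryDay], List[RecallDay]]:
    """Instrument reports for every day of the truth schedule.

    Diary: the truth codes with independent slot misclassification (a
    misclassified slot gets a uniformly random other catalog code).
    Recall: truth slots aggregated to period x intensity class; sub-light
    slots are left unreported (they become the very-light fill at scoring
    time); reported hours are perturbed multiplicatively at the configured
    CV. With probability ``gross_overestimator_prob`` the participant
    reports all waking time as moderate activity. All channels are off under
    :meth:`NoiseConfig.zero`, making the diary a perfect copy of the truth.
    """
    comp = compendium or default_compendium()
    rng = np.random.default_rng(seed)
    codes_all = sorted(a.code for a in comp)
    gross = rng.random() < noise.gross_overestimator_prob
    bias = (1.0 + noise.female_bias) if p.sex == "female" else 1.0

    diary_days: List[DiaryDay] = []
    recall_days: List[RecallDay] = []
    for day_idx, grid in enumerate(grids):
        date = START_DATE + _dt.timedelta(days=day_idx)
        # -- diary channel --
        slots = list(grid)
        if noise.diary_misclass_prob > 0:
            flips = rng.random(len(slots)) < noise.diary_misclass_prob
            for i in np.nonzero(flips)[0]:
                alternatives = [c for c in codes_all if c != slots[i]]
                slots[i] = alternatives[int(rng.integers(len(alternatives)))]
        diary_days.append(DiaryDay(participant_id=p.id, date=date,
                                   slots=tuple(slots)))

        # -- recall channel --
        sleep_hours = sum(1 for c in grid if c in _SLEEP_CODES) * 0.25
        hours: Dict[Tuple[str, str], float] = {}
        for i, code in enumerate(grid):
            if code in _SLEEP_CODES:
                continue
            cls = class_for_mets(lookup_mets(comp, code))
            if cls.name not in SELECTABLE_CLASSES:
                continue  # sub-light time is the unreported residual
            key = (_period_of_slot(i), cls.name)
            hours[key] = hours.get(key, 0.0) + 0.25
        if gross:
            waking: Dict[str, float] = {}
            for i, code in enumerate(grid):
                if code not in _SLEEP_CODES:
                    per = _period_of_slot(i)
                    waking[per] = waking.get(per, 0.0) + 0.25
            hours = {(per, "moderate"): h for per, h in waking.items()}
        entries = []
        for (period, cls_name), h in sorted(hours.items()):
            if noise.recall_hours_cv > 0 and not gross:
                h = max(0.0, h * (1.0 + noise.recall_hours_cv
                                  * rng.standard_normal()))
            h *= bias
            if h > 0:
                entries.append([period, cls_name, h])
        total = sum(e[2] for e in entries)
        budget = 24.0 - sleep_hours
        if total > budget:
            scale = budget / total
            entries = [[per, cls, h * scale] for per, cls, h in entries]
        recall_days.append(RecallDay(
            participant_id=p.id, date=date, sleep_hours=sleep_hours,
            entries=tuple(RecallEntry(per, cls, h) for per, cls, h in entries),
        ))
    return diary_days, recall_days


# ---------------------------------------------------------------------------
# isotope and gas channels
# ---------------------------------------------------------------------------

def _rco2_from_tee(tee_mj_day: float, constants: StudyConstants) -> float:
    """Invert the Weir/RQ route: TEE (MJ/day) -> CO2 production (mol/day)."""
    tee_kcal = tee_mj_day / constants.kcal_to_mj
    kcal_per_l_co2 = (constants.weir_o2_kcal_per_l / constants.rq
                      + constants.weir_co2_kcal_per_l)
    return tee_kcal / kcal_per_l_co2 / constants.co2_molar_volume_l


def render_isotopes(p: SimParticipant, true_tee_mj_week1: float,
                    true_tee_mj_week2: float, noise: NoiseConfig, seed: int,
                    constants: StudyConstants = DEFAULTS
                    ) -> Tuple[List[IsotopeSample], DosingRecord]:
    """Urine enrichment series and dosing record implied by the truth.

    The DLW chain is inverted exactly: each week's TEE fixes that week's CO2
    production and hence k_O given the participant's TBW and k_D; dilution
    spaces follow from the drawn N_d/N_O ratio; doses are the protocol's
    0.12 / 2.5 g per kg predicted TBW. Samples: one baseline at day 0 and
    duplicate pairs on days 1, 8 and 15, with Gaussian analytic noise on the
    delta values at the configured SDs.
    """
    if true_tee_mj_week1 <= 0 or true_tee_mj_week2 <= 0:
        raise ValueError("weekly TEEs must be positive")
    rng = np.random.default_rng(seed)
    tbw = p.tbw_mol
    tbw_kg = tbw * WATER_MOLAR_MASS_G / 1000.0
    dose = DosingRecord(
        participant_id=p.id,
        mass_2h2o_g=DOSE_2H2O_G_PER_KG_TBW * tbw_kg,
        mass_h218o_g=DOSE_H218O_G_PER_KG_TBW * tbw_kg,
    )
    mol_2h, mol_18o = tracer_moles(dose, constants)

    ratio = p.nd_no_ratio
    n_o = 2.0 * tbw / (ratio / constants.dilution_correction_2h
                       + 1.0 / constants.dilution_correction_18o)
    n_d = ratio * n_o
    e0_d = mol_2h / n_d
    e0_o = mol_18o / n_o

    k_d = p.k_d_perday
    k_o = {}
    for week, tee in ((1, true_tee_mj_week1), (2, true_tee_mj_week2)):
        prod = _rco2_from_tee(tee, constants)
        k = ((prod / (constants.rco2_factor * tbw)
              + constants.dilution_correction_2h * k_d)
             / constants.dilution_correction_18o)
        if (constants.dilution_correction_18o * k
                <= constants.dilution_correction_2h * k_d):
            raise ValueError(
                f"infeasible kinetics for {p.id}: TEE week {week} too low "
                f"for k_D = {k_d}"
            )
        k_o[week] = k

    def excess_d(t: float) -> float:
        return e0_d * np.exp(-k_d * t)

    def excess_o(t: float) -> float:
        if t <= 8.0:
            return e0_o * np.exp(-k_o[1] * t)
        return e0_o * np.exp(-k_o[1] * 8.0 - k_o[2] * (t - 8.0))

    base_x_d = delta_to_atom_fraction(BASELINE_DELTA_2H, constants.vsmow_2h_ratio)
    base_x_o = delta_to_atom_fraction(BASELINE_DELTA_18O, constants.vsmow_18o_ratio)

    def make_sample(t: float) -> IsotopeSample:
        if t == 0:
            x_d, x_o = base_x_d, base_x_o
        else:
            x_d = base_x_d + excess_d(t)
            x_o = base_x_o + excess_o(t)
        d2 = atom_fraction_to_delta(x_d, constants.vsmow_2h_ratio)
        d18 = atom_fraction_to_delta(x_o, constants.vsmow_18o_ratio)
        d2 += rng.normal(0.0, noise.sd_delta2h_permil) if noise.sd_delta2h_permil else 0.0
        d18 += rng.normal(0.0, noise.sd_delta18o_permil) if noise.sd_delta18o_permil else 0.0
        return IsotopeSample(time_days=t, delta_2h_permil=d2,
                             delta_18o_permil=d18)

    samples = [make_sample(0.0)]
    for day in SAMPLING_DAYS:
        samples.append(make_sample(day))
        samples.append(make_sample(day))
    return samples, dose


def render_gas_series(p: SimParticipant, seed: int, n_minutes: int = 30,
                      constants: StudyConstants = DEFAULTS) -> GasExchangeSeries:
    """Basal gas-exchange series consistent with the participant's BMR.

    Per-minute VO2 fluctuates around the value implied by BMR at resting
    RQ 0.85; fluctuations are clipped to +/-10 mL/min so the series always
    passes the 25 mL/min steadiness rule.
    """
    rng = np.random.default_rng(seed)
    bmr_kcal = p.bmr_mj_day / constants.kcal_to_mj
    vo2_l_day = bmr_kcal / (constants.weir_o2_kcal_per_l
                            + constants.weir_co2_kcal_per_l * constants.rq)
    vo2_mean = vo2_l_day * 1000.0 / 1440.0
    wobble = np.clip(rng.normal(0.0, 3.0, size=n_minutes), -10.0, 10.0)
    vo2 = vo2_mean + wobble
    vco2 = constants.rq * vo2
    return GasExchangeSeries(
        participant_id=p.id,
        minutes=tuple(range(n_minutes)),
        vo2_ml_min=tuple(float(v) for v in vo2),
        vco2_ml_min=tuple(float(v) for v in vco2),
    )


# ---------------------------------------------------------------------------
# whole-study bundle
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """Everything one simulated study produces, keyed by participant id."""

    participants: List[SimParticipant]
    assignment: Dict[str, Tuple[str, str]]
    schedules: Dict[str, List[Tuple[str, ...]]]
    diary_days: Dict[str, List[DiaryDay]]
    recall_days: Dict[str, List[RecallDay]]
    isotope_samples: Dict[str, List[IsotopeSample]]
    doses: Dict[str, DosingRecord]
    gas_series: Dict[str, GasExchangeSeries]
    truth: Dict[str, Dict[str, float]]
    seed: int
    noise: NoiseConfig


def simulate_study(n: int = 20, seed: int = 0,
                   noise: Optional[NoiseConfig] = None,
                   constants: StudyConstants = DEFAULTS) -> StudyData:
    """Simulate the full 14-day crossover study for ``n`` participants.

    Week 1 is days 0-6 of the schedule, week 2 days 7-13; each participant's
    instrument reports cover all 14 days and the caller (or the pipeline)
    selects the assigned week per instrument. Weekly truth TEE is the mean
    daily TEE of the truth schedule under the diary conversion.
    """
    noise = noise if noise is not None else NoiseConfig()
    participants, assignment = generate_cohort(n, seed)
    rng = np.random.default_rng(seed + 1)
    sub_seeds = rng.integers(0, 2**31 - 1, size=(n, 4))

    data = StudyData(participants=participants, assignment=assignment,
                     schedules={}, diary_days={}, recall_days={},
                     isotope_samples={}, doses={}, gas_series={}, truth={},
                     seed=seed, noise=noise)
    comp = default_compendium()
    for i, p in enumerate(participants):
        s0, s1, s2, s3 = (int(s) for s in sub_seeds[i])
        sched = generate_true_schedule(p, 14, s0, comp, constants)
        bmr_kcal = p.bmr_mj_day / constants.kcal_to_mj
        daily_tee = []
        for grid in sched:
            avg = sum(lookup_mets(comp, c) for c in grid) / SLOTS_PER_DAY
            daily_tee.append(bmr_kcal * avg * constants.sitting_factor
                             / constants.dit_factor * constants.kcal_to_mj)
        tee_w1 = float(np.mean(daily_tee[:7]))
        tee_w2 = float(np.mean(daily_tee[7:]))

        diary, recall = render_reports(sched, p, noise, s1, comp)
        iso, dose = render_isotopes(p, tee_w1, tee_w2, noise, s2, constants)
        gas = render_gas_series(p, s3, constants=constants)

        data.schedules[p.id] = sched
        data.diary_days[p.id] = diary
        data.recall_days[p.id] = recall
        data.isotope_samples[p.id] = iso
        data.doses[p.id] = dose
        data.gas_series[p.id] = gas
        data.truth[p.id] = {
            "tee_mj_week1": tee_w1,
            "tee_mj_week2": tee_w2,
            "bmr_mj_day": p.bmr_mj_day,
            "true_pal": p.true_pal,
            "nd_no_ratio": p.nd_no_ratio,
        }
    return data
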