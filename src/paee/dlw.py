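"""Doubly labeled water (DLW) reference calculations.

The chain implemented here:

1. dose masses of 2H2O and H2(18)O -> moles of excess tracer (mass balance
   against natural abundance);
2. urine delta-permil enrichment series -> per-isotope elimination rate k and
   time-zero enrichment excess by log-linear back-extrapolation (the
   intercept method);
3. dilution spaces N = tracer moles / time-zero excess; total body water
   TBW = mean(N_d / 1.041, N_O / 1.007);
4. CO2 production rCO2 = 0.4554 * TBW * (1.007 k_O - 1.041 k_D) [mol/day];
5. energy: VCO2 from rCO2 via the molar volume, VO2 = VCO2 / RQ (RQ assumed
   0.85), TEE from the abbreviated Weir equation; PAL = TEE / BMR.

Enrichments are converted from delta-permil (vs VSMOW) to atom fractions
before any subtraction; excess is formed in mole-fraction space. Because both
the dose and body water carry two hydrogen atoms per molecule, expressing the
2H tracer as "moles of labeled water equivalent" (per exchange site) makes
N = moles / excess an amount of body water for both isotopes.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .calorimetry import weir_ee_kcal_per_day
from .constants import (DEFAULTS, MASS_16O, MASS_18O, MASS_1H, MASS_2H,
                        MASS_H_NATURAL, MASS_O_NATURAL, StudyConstants)


class BaselineViolationError(ValueError):
    """Post-dose enrichment at or below baseline."""


class InsufficientDataError(ValueError):
    """Too few samples for the requested fit."""


class NegativeProductionError(ValueError):
    """1.007 k_O <= 1.041 k_D: swapped isotopes or a failed fit."""


class DLWQualityWarning(UserWarning):
    """Dilution-space ratio outside the plausibility band."""


@dataclass(frozen=True)
class DosingRecord:
    """Administered tracer doses.

    Masses are grams of labeled water as drunk; atom percents are the isotopic
    purity of each dose (protocol defaults 99.8 atom% 2H, 10.0 atom% 18O).
    """

    participant_id: str
    mass_2h2o_g: float
    mass_h218o_g: float
    atom_pct_2h: float = 99.8
    atom_pct_18o: float = 10.0
    dose_time: Optional[_dt.datetime] = None

    def __post_init__(self):
        if self.mass_2h2o_g <= 0 or self.mass_h218o_g <= 0:
            raise ValueError("dose masses must be positive")
        for pct in (self.atom_pct_2h, self.atom_pct_18o):
            if not (0 < pct <= 100):
                raise ValueError(f"atom percent must be in (0, 100], got {pct}")


@dataclass(frozen=True)
class IsotopeSample:
    """One urine sample: days since dose (0 = pre-dose baseline) and
    delta-permil enrichments vs VSMOW for both isotopes."""

    time_days: float
    delta_2h_permil: float
    delta_18o_permil: float

    def __post_init__(self):
        if self.time_days < 0:
            raise ValueError("time_days must be >= 0")


@dataclass(frozen=True)
class DilutionSpaces:
    n_d_mol: float
    n_o_mol: float
    tbw_mol: float
    nd_no_ratio: float
    qc_ok: bool


@dataclass(frozen=True)
class DLWResult:
    """Full per-week DLW output."""

    n_d_mol: float
    n_o_mol: float
    tbw_mol: float
    k_d_perday: float
    k_o_perday: float
    rco2_mol_day: float
    tee_mj_day: float
    pal: float
    nd_no_ratio: float
    qc_ok: bool
    week: int


# ---------------------------------------------------------------------------
# enrichment conversions
# ---------------------------------------------------------------------------

def delta_to_atom_fraction(delta_permil: float, vsmow_ratio: float) -> float:
    """delta-permil vs VSMOW -> atom fraction of the rare isotope."""
    ratio = vsmow_ratio * (1.0 + delta_permil / 1000.0)
    return ratio / (1.0 + ratio)


def atom_fraction_to_delta(fraction: float, vsmow_ratio: float) -> float:
    """Inverse of :func:`delta_to_atom_fraction`."""
    ratio = fraction / (1.0 - fraction)
    return (ratio / vsmow_ratio - 1.0) * 1000.0


def labeled_water_molar_mass(isotope: str, atom_fraction: float) -> float:
    """Molar mass (g/mol) of water enriched to ``atom_fraction`` in one
    isotope ('2H' or '18O'), the other element at natural composition."""
    if isotope == "2H":
        return 2.0 * (atom_fraction * MASS_2H
                      + (1.0 - atom_fraction) * MASS_1H) + MASS_O_NATURAL
    if isotope == "18O":
        return (2.0 * MASS_H_NATURAL + atom_fraction * MASS_18O
                + (1.0 - atom_fraction) * MASS_16O)
    raise ValueError(f"isotope must be '2H' or '18O', got {isotope!r}")


def tracer_moles(dose: DosingRecord,
                 constants: StudyConstants = DEFAULTS) -> Tuple[float, float]:
    """Moles of excess tracer delivered by each dose.

    Returned as moles of labeled-water equivalent: dose mass / molar mass of
    the labeled water x (dose atom fraction - natural atom fraction). For 2H
    the two hydrogen sites per molecule cancel between dose and body-water
    pool, so dividing by the per-site enrichment excess yields mol of body
    water directly.
    """
    a_d = dose.atom_pct_2h / 100.0
    a_o = dose.atom_pct_18o / 100.0
    mol_2h = (dose.mass_2h2o_g / labeled_water_molar_mass("2H", a_d)
              * (a_d - constants.natural_2h_fraction))
    mol_18o = (dose.mass_h218o_g / labeled_water_molar_mass("18O", a_o)
               * (a_o - constants.natural_18o_fraction))
    return mol_2h, mol_18o


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def _split_baseline(samples: Sequence[IsotopeSample]):
    baseline = [s for s in samples if s.time_days == 0]
    post = sorted((s for s in samples if s.time_days > 0),
                  key=lambda s: s.time_days)
    if not baseline:
        raise InsufficientDataError("no pre-dose (time 0) baseline sample")
    return baseline, post


def excess_series(samples: Sequence[IsotopeSample], isotope: str,
                  constants: StudyConstants = DEFAULTS
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Times (days) and mole-fraction enrichment excesses above baseline
    for all post-dose samples, in time order.

    The baseline is the mean atom fraction of the pre-dose (time 0) samples;
    excess is formed by subtraction in atom-fraction space, not delta space.
    """
    if isotope == "2H":
        vsmow = constants.vsmow_2h_ratio
        get = lambda s: s.delta_2h_permil
    elif isotope == "18O":
        vsmow = constants.vsmow_18o_ratio
        get = lambda s: s.delta_18o_permil
    else:
        raise ValueError(f"isotope must be '2H' or '18O', got {isotope!r}")
    baseline, post = _split_baseline(samples)
    base_frac = float(np.mean([delta_to_atom_fraction(get(s), vsmow)
                               for s in baseline]))
    times = np.array([s.time_days for s in post], dtype=float)
    excess = np.array([delta_to_atom_fraction(get(s), vsmow) - base_frac
                       for s in post])
    if np.any(excess <= 0):
        bad = times[excess <= 0]
        raise BaselineViolationError(
            f"{isotope} enrichment at day(s) {bad.tolist()} not above baseline"
        )
    return times, excess


def fit_elimination(samples: Sequence[IsotopeSample], isotope: str,
                    window: Optional[Tuple[float, float]] = None,
                    constants: StudyConstants = DEFAULTS
                    ) -> Tuple[float, float]:
    """Elimination rate and time-zero intercept by log-linear OLS.

    Ordinary least squares of ln(excess mole fraction) on time over the
    post-dose samples in ``window`` (inclusive bounds; all post-dose samples
    when None). Duplicate samples at a time point enter as separate
    observations. Returns (k_perday, excess0) with k = -slope and
    excess0 = exp(intercept).
    """
    times, excess = excess_series(samples, isotope, constants)
    if window is not None:
        t0, t1 = window
        keep = (times >= t0) & (times <= t1)
        times, excess = times[keep], excess[keep]
    if times.size < 2:
        raise InsufficientDataError(
            f"need >= 2 post-dose samples in window, got {times.size}"
        )
    slope, intercept = np.polyfit(times, np.log(excess), 1)
    return -float(slope), float(np.exp(intercept))


def dilution_spaces(dose: DosingRecord, excess0_2h: float, excess0_18o: float,
                    constants: StudyConstants = DEFAULTS) -> DilutionSpaces:
    """Dilution spaces, TBW and the N_d/N_O quality ratio.

    N = tracer moles / time-zero excess per isotope;
    TBW = mean(N_d / 1.041, N_O / 1.007). A ratio outside the plausibility
    band raises :class:`DLWQualityWarning` but the result is still returned.
    """
    if excess0_2h <= 0 or excess0_18o <= 0:
        raise ValueError("time-zero excesses must be positive")
    mol_2h, mol_18o = tracer_moles(dose, constants)
    n_d = mol_2h / excess0_2h
    n_o = mol_18o / excess0_18o
    tbw = 0.5 * (n_d / constants.dilution_correction_2h
                 + n_o / constants.dilution_correction_18o)
    ratio = n_d / n_o
    lo, hi = constants.nd_no_band
    qc_ok = lo <= ratio <= hi
    if not qc_ok:
        warnings.warn(
            f"N_d/N_O = {ratio:.4f} outside plausibility band [{lo}, {hi}] "
            f"for participant {dose.participant_id}",
            DLWQualityWarning,
            stacklevel=2,
        )
    return DilutionSpaces(n_d_mol=n_d, n_o_mol=n_o, tbw_mol=tbw,
                          nd_no_ratio=ratio, qc_ok=qc_ok)


def rco2(tbw_mol: float, k_o_perday: float, k_d_perday: float,
         constants: StudyConstants = DEFAULTS) -> float:
    """CO2 production rate, mol/day.

    rCO2 = 0.4554 * TBW * (1.007 k_O - 1.041 k_D); the constants embody the
    standard breath-water fractionation corrections and revised dilution-space
    proportions.
    """
    if tbw_mol <= 0 or k_o_perday <= 0 or k_d_perday < 0:
        raise ValueError("TBW and k_O must be positive, k_D non-negative")
    bracket = (constants.dilution_correction_18o * k_o_perday
               - constants.dilution_correction_2h * k_d_perday)
    if bracket < 0:
        raise NegativeProductionError(
            f"1.007 k_O ({constants.dilution_correction_18o * k_o_perday:.5f}) "
            f"< 1.041 k_D ({constants.dilution_correction_2h * k_d_perday:.5f})"
        )
    return constants.rco2_factor * tbw_mol * bracket


def tee_from_rco2(rco2_mol_day: float, rq: Optional[float] = None,
                  constants: StudyConstants = DEFAULTS) -> float:
    """TEE (MJ/day) from CO2 production via the modified Weir route.

    VCO2 [L/d] = rCO2 x molar volume; VO2 = VCO2 / RQ; energy from the
    abbreviated Weir equation, converted kcal -> MJ.
    """
    if rco2_mol_day < 0:
        raise ValueError("rCO2 must be non-negative")
    rq = constants.rq if rq is None else rq
    if not (0.6 < rq < 1.1):
        raise ValueError(f"respiratory quotient {rq} outside (0.6, 1.1)")
    vco2_l_day = rco2_mol_day * constants.co2_molar_volume_l
    vo2_l_day = vco2_l_day / rq
    return weir_ee_kcal_per_day(vo2_l_day, vco2_l_day, constants) * constants.kcal_to_mj


# ---------------------------------------------------------------------------
# weekly assembly
# ---------------------------------------------------------------------------

#: Nominal sampling days for each observation week: (start day, end day).
WEEK_ENDPOINTS = {1: (1.0, 8.0), 2: (8.0, 15.0)}


def _day_mean(times: np.ndarray, excess: np.ndarray, day: float,
              tol: float = 0.5) -> Tuple[float, float]:
    """Mean time and mean excess of the duplicate samples nearest ``day``."""
    mask = np.abs(times - day) <= tol
    if not mask.any():
        raise InsufficientDataError(f"no sample near day {day:g}")
    return float(times[mask].mean()), float(excess[mask].mean())


def dlw_week(samples: Sequence[IsotopeSample], dose: DosingRecord,
             bmr_mj_day: float, week: int,
             constants: StudyConstants = DEFAULTS) -> DLWResult:
    """Assemble the full DLW result for observation week 1 or 2.

    Dilution spaces (hence TBW) come from the intercept fit over all
    post-dose samples; the week's elimination rates are two-point log slopes
    between the endpoint days of that week (day 1 -> 8 or 8 -> 15), with
    same-day duplicates averaged before the slope.
    """
    if week not in WEEK_ENDPOINTS:
        raise ValueError(f"week must be 1 or 2, got {week}")
    if bmr_mj_day <= 0:
        raise ValueError("BMR must be positive (MJ/day)")
    d0, d1 = WEEK_ENDPOINTS[week]

    rates = {}
    intercepts = {}
    for isotope in ("2H", "18O"):
        times, excess = excess_series(samples, isotope, constants)
        _, e0 = fit_elimination(samples, isotope, constants=constants)
        intercepts[isotope] = e0
        ta, ea = _day_mean(times, excess, d0)
        tb, eb = _day_mean(times, excess, d1)
        if tb <= ta:
            raise InsufficientDataError(
                f"week {week} endpoints collapse: days {ta:g}, {tb:g}"
            )
        rates[isotope] = (np.log(ea) - np.log(eb)) / (tb - ta)

    spaces = dilution_spaces(dose, intercepts["2H"], intercepts["18O"], constants)
    prod = rco2(spaces.tbw_mol, rates["18O"], rates["2H"], constants)
    tee = tee_from_rco2(prod, constants=constants)
    return DLWResult(
        n_d_mol=spaces.n_d_mol,
        n_o_mol=spaces.n_o_mol,
        tbw_mol=spaces.tbw_mol,
        k_d_perday=rates["2H"],
        k_o_perday=rates["18O"],
        rco2_mol_day=prod,
        tee_mj_day=tee,
        pal=tee / bmr_mj_day,
        nd_no_ratio=spaces.nd_no_ratio,
        qc_ok=spaces.qc_ok,
        week=week,
    )
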