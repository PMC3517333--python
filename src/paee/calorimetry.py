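"""Basal metabolic rate from indirect-calorimetry gas exchange.

Energy expenditure is computed from O2 consumption and CO2 production with
the abbreviated (protein-free) Weir equation. A basal collection is accepted
only if VO2 is steady: its range within the averaging window must stay below
25 mL/min.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .constants import DEFAULTS, StudyConstants

MIN_SAMPLES = 5
_ML_MIN_TO_L_DAY = 1440.0 / 1000.0


class InsufficientDataError(ValueError):
    """Raised when a gas series is too short for the requested window."""


@dataclass(frozen=True)
class GasExchangeSeries:
    """Per-minute VO2/VCO2 series for one participant (mL/min)."""

    participant_id: str
    minutes: tuple
    vo2_ml_min: tuple
    vco2_ml_min: tuple

    def __post_init__(self):
        object.__setattr__(self, "minutes", tuple(self.minutes))
        object.__setattr__(self, "vo2_ml_min", tuple(self.vo2_ml_min))
        object.__setattr__(self, "vco2_ml_min", tuple(self.vco2_ml_min))
        n = len(self.minutes)
        if not (n == len(self.vo2_ml_min) == len(self.vco2_ml_min)):
            raise ValueError("minute/VO2/VCO2 lengths differ")
        if n < MIN_SAMPLES:
            raise ValueError(f"need >= {MIN_SAMPLES} samples, got {n}")
        if any(b <= a for a, b in zip(self.minutes, self.minutes[1:])):
            raise ValueError("minute indices must be strictly increasing")
        if min(self.vo2_ml_min) <= 0 or min(self.vco2_ml_min) <= 0:
            raise ValueError("gas volumes must be positive")


@dataclass(frozen=True)
class BMRResult:
    bmr_kcal_day: float
    bmr_mj_day: float
    accepted: bool
    vo2_range_ml_min: float
    window: Tuple[int, int]  # [start, stop) sample indices used


def weir_ee_kcal_per_day(vo2_l_day: float, vco2_l_day: float,
                         constants: StudyConstants = DEFAULTS) -> float:
    """Abbreviated Weir: EE [kcal/d] = 3.941 VO2 + 1.106 VCO2 (L/day)."""
    if vo2_l_day < 0 or vco2_l_day < 0:
        raise ValueError("gas volumes must be non-negative")
    return (constants.weir_o2_kcal_per_l * vo2_l_day
            + constants.weir_co2_kcal_per_l * vco2_l_day)


def bmr_from_series(series: GasExchangeSeries,
                    steady_window_min: Optional[int] = None,
                    constants: StudyConstants = DEFAULTS) -> BMRResult:
    """BMR from a gas series, with the VO2-steadiness acceptance rule.

    The averaging window is the last contiguous run of ``steady_window_min``
    samples whose VO2 range (max - min) is below the acceptance threshold;
    if no window qualifies, the last window is used and the collection is
    flagged as not accepted. With ``steady_window_min`` None the whole series
    is the window.
    """
    vo2 = np.asarray(series.vo2_ml_min, dtype=float)
    vco2 = np.asarray(series.vco2_ml_min, dtype=float)
    n = vo2.size
    limit = constants.vo2_steadiness_ml_min

    if steady_window_min is None:
        start, stop = 0, n
    else:
        w = int(steady_window_min)
        if w < 2:
            raise ValueError("steady_window_min must be >= 2 samples")
        if w > n:
            raise InsufficientDataError(
                f"series has {n} samples, window needs {w}"
            )
        start, stop = n - w, n  # fallback: last window
        for s in range(n - w, -1, -1):
            seg = vo2[s:s + w]
            if seg.max() - seg.min() < limit:
                start, stop = s, s + w
                break

    seg_vo2 = vo2[start:stop]
    seg_vco2 = vco2[start:stop]
    vo2_range = float(seg_vo2.max() - seg_vo2.min())
    accepted = vo2_range < limit
    vo2_l_day = float(seg_vo2.mean()) * _ML_MIN_TO_L_DAY
    vco2_l_day = float(seg_vco2.mean()) * _ML_MIN_TO_L_DAY
    kcal = weir_ee_kcal_per_day(vo2_l_day, vco2_l_day, constants)
    return BMRResult(
        bmr_kcal_day=kcal,
        bmr_mj_day=kcal * constants.kcal_to_mj,
        accepted=accepted,
        vo2_range_ml_min=vo2_range,
        window=(start, stop),
    )
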