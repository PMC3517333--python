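"""Physical and protocol constants used throughout the package.

Every scoring/kinetics constant lives here so that a study configuration can
override it in one place; computational modules take a :class:`StudyConstants`
argument defaulting to :data:`DEFAULTS` and never embed these literals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

# Atomic masses (u), needed for tracer mass balance.
MASS_1H = 1.0078250319
MASS_2H = 2.0141017779
MASS_16O = 15.9949146221
MASS_18O = 17.9991604
MASS_O_NATURAL = 15.9994  # natural-abundance oxygen
MASS_H_NATURAL = 1.00794  # natural-abundance hydrogen
WATER_MOLAR_MASS_G = 18.01528  # natural water, g/mol


@dataclass(frozen=True)
class StudyConstants:
    """Bundle of every tunable constant with its protocol default.

    Attributes
    ----------
    sitting_factor : float
        Ratio of sitting resting metabolic rate to supine fasting BMR; the
        diary MET scale is anchored at sitting rest, so 24-h average METs
        multiply BMR by this factor (default 1.1).
    dit_factor : float
        Fraction of total energy expenditure remaining after diet-induced
        thermogenesis (~10%), i.e. TEE is divided by this to add DIT and
        multiplied by it when isolating the activity component (default 0.9).
    kcal_to_mj : float
        kilocalorie to megajoule conversion (4.184e-3).
    weir_o2_kcal_per_l, weir_co2_kcal_per_l : float
        Coefficients of the abbreviated (protein-free) Weir equation,
        EE [kcal] = 3.941 VO2 [L] + 1.106 VCO2 [L].
    rq : float
        Respiratory quotient assumed when converting CO2 production to O2
        consumption for the DLW energy calculation (default 0.85).
    co2_molar_volume_l : float
        Molar volume used to convert mol CO2/day to L/day (ideal-gas STP
        22.414; the real-gas alternative 22.26 may be configured).
    vsmow_2h_ratio, vsmow_18o_ratio : float
        VSMOW absolute isotope ratios (2H/1H and 18O/16O) used to convert
        delta-permil enrichments to atom fractions.
    dilution_correction_2h, dilution_correction_18o : float
        Dilution-space overestimation factors: TBW = mean(N_d/1.041,
        N_O/1.007).
    rco2_factor : float
        Leading constant of the CO2 production equation
        rCO2 = 0.4554 * TBW * (1.007 k_O - 1.041 k_D), which embodies the
        standard breath-water fractionation assumptions.
    vo2_steadiness_ml_min : float
        Maximum allowed VO2 range (max - min, mL/min) within the averaging
        window for a basal gas collection to be accepted (default 25).
    loa_multiplier : float
        Half-width multiplier for Bland-Altman limits of agreement (1.96 SD).
    alpha : float
        Significance threshold reported alongside p-values (default .01).
    nd_no_band : tuple
        Plausibility band for the dilution-space ratio N_d/N_O; results
        outside it are flagged, never suppressed.
    """

    sitting_factor: float = 1.1
    dit_factor: float = 0.9
    kcal_to_mj: float = 4.184e-3
    weir_o2_kcal_per_l: float = 3.941
    weir_co2_kcal_per_l: float = 1.106
    rq: float = 0.85
    co2_molar_volume_l: float = 22.414
    vsmow_2h_ratio: float = 155.76e-6
    vsmow_18o_ratio: float = 2005.20e-6
    dilution_correction_2h: float = 1.041
    dilution_correction_18o: float = 1.007
    rco2_factor: float = 0.4554
    vo2_steadiness_ml_min: float = 25.0
    loa_multiplier: float = 1.96
    alpha: float = 0.01
    nd_no_band: Tuple[float, float] = (1.000, 1.070)

    def override(self, **kwargs) -> "StudyConstants":
        """Return a copy with the given constants replaced."""
        return replace(self, **kwargs)

    @property
    def natural_2h_fraction(self) -> float:
        """Natural 2H atom fraction implied by the VSMOW ratio."""
        r = self.vsmow_2h_ratio
        return r / (1.0 + r)

    @property
    def natural_18o_fraction(self) -> float:
        """Natural 18O atom fraction implied by the VSMOW ratio."""
        r = self.vsmow_18o_ratio
        return r / (1.0 + r)


DEFAULTS = StudyConstants()
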