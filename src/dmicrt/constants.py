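"""Physical constants used throughout the package.

Gyromagnetic ratios are CODATA values.  Deuterium resonates at
``GAMMA_2H_MHZ_PER_T * B0`` MHz, i.e. ~45.75 MHz at 7 T, so one ppm of
chemical shift or field inhomogeneity corresponds to ~45.75 Hz for ²H.
"""

GAMMA_1H_MHZ_PER_T = 42.577478461
GAMMA_2H_MHZ_PER_T = 6.535902311

#: gamma_2H / gamma_1H, used to rescale proton field maps to deuterium Hz.
GAMMA_RATIO_2H_1H = GAMMA_2H_MHZ_PER_T / GAMMA_1H_MHZ_PER_T

DEFAULT_FIELD_STRENGTH_T = 7.0

#: Natural abundance of deuterium among hydrogen nuclei.
NATURAL_ABUNDANCE_2H = 0.0156e-2

#: Concentration of naturally abundant semi-heavy water (HDO) in pure water.
#: 110.4 M hydrogen * 0.0156 % ~= 17.2 mM.
PURE_WATER_D_CONCENTRATION_MM = 17.2


def larmor_2h_mhz(field_strength_t: float = DEFAULT_FIELD_STRENGTH_T) -> float:
    """Deuterium Larmor frequency in MHz at the given field strength."""
    return GAMMA_2H_MHZ_PER_T * field_strength_t


def ppm_to_hz(ppm: float, field_strength_t: float = DEFAULT_FIELD_STRENGTH_T) -> float:
    """Convert a chemical-shift/field offset in ppm to deuterium Hz."""
    return ppm * larmor_2h_mhz(field_strength_t)
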