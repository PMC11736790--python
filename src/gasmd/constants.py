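"""Physical constants and unit conversions.

Internal unit system: length in Å, time in fs, mass in amu, temperature in K.
The derived energy unit is amu·Å²·fs⁻² and the derived pressure unit is
amu·Å⁻¹·fs⁻².  All constants are CODATA 2018; every route-equivalence test in
the suite relies on this module being the single source of truth.
"""

# CODATA 2018 exact / recommended values (SI)
BOLTZMANN_J = 1.380649e-23  # J/K (exact)
AVOGADRO = 6.02214076e23  # 1/mol (exact)
ATOMIC_MASS_KG = 1.66053906660e-27  # kg

#: one internal energy unit (amu·Å²/fs²) in joule
INTERNAL_ENERGY_J = ATOMIC_MASS_KG * 1e-20 / 1e-30

#: Boltzmann constant in amu·Å²·fs⁻²·K⁻¹
KB = BOLTZMANN_J / INTERNAL_ENERGY_J

#: kJ/mol expressed in internal energy units (≈1e-4)
KJ_PER_MOL = (1000.0 / AVOGADRO) / INTERNAL_ENERGY_J

#: one internal pressure unit (amu·Å⁻¹·fs⁻²) in bar
PRESSURE_TO_BAR = INTERNAL_ENERGY_J / 1e-30 / 1e5

#: universal gas constant in L·bar·mol⁻¹·K⁻¹ (for the van der Waals EOS)
R_L_BAR = BOLTZMANN_J * AVOGADRO / 100.0

#: litres per mole from Å³ per molecule
ANG3_TO_L_PER_MOL = AVOGADRO * 1e-27

# IUPAC 2021 standard atomic weights (amu), conventional values
ATOMIC_MASSES = {
    "H": 1.008,
    "He": 4.002602,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Ne": 20.1797,
    "S": 32.06,
    "Ar": 39.948,
    "Kr": 83.798,
    "Xe": 131.293,
}
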