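"""Physical constants in the package's internal units (nm, amu, kJ/mol, K)."""

GAS_CONSTANT_KJ = 8.314462618e-3  # kJ mol^-1 K^-1 (molar Boltzmann constant)

# 1 amu / nm^3 expressed in kg / m^3
AMU_PER_NM3_TO_KG_M3 = 1.66053906892

LN10 = 2.302585092994046
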