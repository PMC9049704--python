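"""Physical constants in the package unit system.

Units throughout: length Å, time ps, mass amu, energy kcal mol⁻¹,
charge in units of the elementary charge e.
"""

#: Boltzmann constant, kcal mol⁻¹ K⁻¹ (MD convention; 300 K ≈ 0.5962 kcal mol⁻¹).
KB = 0.0019872

#: Coulomb constant, kcal Å mol⁻¹ e⁻².
COULOMB_K = 332.0636

#: Conversion factor: 1 kcal mol⁻¹ expressed in amu Å² ps⁻².
#: (1 amu Å²/ps² = 10 J/mol exactly, with amu = 1 g/mol.)
KCAL_TO_INTERNAL = 418.4


def kbt(temperature: float) -> float:
    """k_B·T in kcal mol⁻¹ at the given temperature (K)."""
    return KB * temperature
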