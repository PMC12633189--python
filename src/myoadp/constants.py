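"""Physical constants in the unit system used throughout the package.

Energies are kcal/mol, lengths Å, times ps, temperatures K. Entropies are
reported in cal mol⁻¹ K⁻¹, the convention for dihedral-map conformational
entropies of bound nucleotides.
"""

#: Boltzmann constant / gas constant, kcal mol⁻¹ K⁻¹
KB_KCAL = 1.987204259e-3

#: Gas constant in cal mol⁻¹ K⁻¹ (entropy unit convention)
R_CAL = 1.987204259

#: Coulomb constant, kcal Å mol⁻¹ e⁻²
COULOMB_CONSTANT = 332.0636

#: Simulation temperature of the study conditions, K
DEFAULT_TEMPERATURE = 310.0


def kT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy in kcal/mol at ``temperature`` (≈0.616 kcal/mol at 310 K)."""
    return KB_KCAL * temperature
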