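"""Physical constants and unit conversions used across the package.

Energies are kJ/mol, distances nm (sampling) or Å (structures), times ns,
forces pN in user-facing output and kJ/mol/nm in raw records.
"""

#: Boltzmann constant in kJ/mol/K.
KB = 0.0083145

#: 1 kJ/mol/nm expressed in pN.
PN_PER_KJ_MOL_NM = 1.66054


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return KB * temperature


def force_to_pn(force_kj_mol_nm):
    """Convert a force from kJ/mol/nm to pN."""
    return force_kj_mol_nm * PN_PER_KJ_MOL_NM
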