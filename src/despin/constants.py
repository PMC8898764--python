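"""Physical constants in the spectroscopist's unit system.

Energies are wavenumbers (cm^-1), temperatures kelvin, magnetic fields tesla,
magnetic moments Bohr magnetons per molecule, molar susceptibility-temperature
products cm^3 K mol^-1 (identical to emu K mol^-1 in CGS usage).
"""

#: Boltzmann constant, cm^-1 K^-1.
KB_CM: float = 0.6950348

#: Bohr magneton, cm^-1 T^-1 (mu_B / hc).
MUB_CM_PER_T: float = 0.46686

#: Curie prefactor N_A mu_B^2 / (3 k_B), cm^3 K mol^-1.
#: chi_M T of an isolated spin S is CURIE_C * g^2 * S(S+1).
CURIE_C: float = 0.125049

#: N_A mu_B expressed as emu mol^-1 T^-1: converts a molecular moment in mu_B
#: divided by the field in tesla into molar CGS susceptibility (cm^3 mol^-1).
# N_A mu_B = 5585 erg G^-1 mol^-1; 1 T = 1e4 G; chi = N_A mu_B M / H gives
# 5585 * M[mu_B] / (1e4 * B[T]) cm^3 mol^-1 -> factor 0.5585 per tesla.
NA_MUB_EMU_PER_T: float = 0.55849

#: Free-electron g value.
G_E: float = 2.0023

#: Bohr magneton, J T^-1 (SI, for nutation frequencies).
MUB_SI: float = 9.2740100783e-24

#: Reduced Planck constant, J s.
HBAR_SI: float = 1.054571817e-34
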