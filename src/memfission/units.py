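"""Unit system and physical constants.

Internal units throughout the package: length in Å, time in ps, energy in
units of k_BT at the simulation temperature (310 K by default). Quantities
native to GROMACS-style inputs (nm, kJ/mol) are converted at the boundary.
"""

# CODATA molar gas constant, kJ mol^-1 K^-1
R_KJ_PER_MOL_K = 8.31446261815324e-3

#: Default simulation temperature, K (velocity-rescaling thermostat target).
DEFAULT_TEMPERATURE_K = 310.0

#: RT at 310 K, kJ/mol. One k_BT of energy per particle == RT per mole.
RT_KJ_PER_MOL_310K = R_KJ_PER_MOL_K * DEFAULT_TEMPERATURE_K  # 2.577483411627504

NM_TO_ANGSTROM = 10.0
ANGSTROM_TO_NM = 0.1

#: 1 Å² ps⁻¹ = 1e-20 m² / 1e-12 s = 1e-8 m²/s = 1e4 μm²/s
A2_PER_PS_TO_UM2_PER_S = 1.0e4
UM2_PER_S_TO_A2_PER_PS = 1.0e-4

NS_TO_PS = 1000.0
PS_TO_NS = 1.0e-3


def kbt_per_kj_mol(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Energy conversion factor: multiply an energy in kJ/mol by this to get k_BT."""
    return 1.0 / (R_KJ_PER_MOL_K * temperature_k)


def force_constant_to_internal(k_kj_mol_nm2: float,
                               temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Convert a harmonic force constant from kJ mol⁻¹ nm⁻² to k_BT Å⁻².

    k[k_BT/Å²] = k[kJ/mol/nm²] / (RT[kJ/mol] × 100 Å²/nm²).
    For 2000 kJ mol⁻¹ nm⁻² at 310 K this gives ≈ 7.7595 k_BT Å⁻².
    """
    return k_kj_mol_nm2 / (R_KJ_PER_MOL_K * temperature_k) / 100.0
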