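"""Physical constants and unit conversions.

Internal units throughout the package: kcal·mol⁻¹ (energy), Å (length),
elementary charge e (charge), K (temperature), amu (mass).

All fundamental constants are pinned to CODATA-2018 exact/recommended values so
that every derived number (Coulomb energies, TST prefactors, vibrational
frequencies) is bit-reproducible across platforms.
"""

from __future__ import annotations

# --- CODATA-2018 fundamental constants (SI) ---
BOLTZMANN_SI = 1.380649e-23  # J/K (exact)
PLANCK_SI = 6.62607015e-34  # J·s (exact)
AVOGADRO = 6.02214076e23  # 1/mol (exact)
SPEED_OF_LIGHT_CM = 2.99792458e10  # cm/s (exact)

# --- derived / conventional ---
KCAL_TO_J = 4184.0  # thermochemical calorie
GAS_CONSTANT_KCAL = BOLTZMANN_SI * AVOGADRO / KCAL_TO_J  # kcal·mol⁻¹·K⁻¹
ATM_TO_PA = 101325.0

#: Coulomb constant in kcal·Å·mol⁻¹·e⁻², fixed (not recomputed from CODATA) so
#: that electrostatic energies are identical across implementations.
COULOMB_KCAL = 332.0637

#: Default thermodynamic state.
DEFAULT_TEMPERATURE = 298.15  # K
DEFAULT_PRESSURE_ATM = 1.0

#: Conversion factor: Hessian eigenvalue in kcal·mol⁻¹·Å⁻²·amu⁻¹ → angular
#: frequency squared in s⁻².  1 kcal/mol = 4184/N_A J; 1 Å² = 1e-20 m²;
#: 1 amu = 1e-3/N_A kg.
HESSIAN_EIGVAL_TO_OMEGA_SQ = KCAL_TO_J * 1.0e23 / 1.0e20  # = 4.184e26 ... see below
# (kcal/mol)/(Å²·amu) = (4184/N_A J) / (1e-20 m² · (1e-3/N_A) kg) = 4.184e26 s⁻²
HESSIAN_EIGVAL_TO_OMEGA_SQ = 4184.0 / (1.0e-20 * 1.0e-3)  # 4.184e26 s⁻²

#: Atomic masses (amu), most-abundant-isotope-weighted standard weights.
ATOMIC_MASSES = {
    "H": 1.00794,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "Cl": 35.45,
}

#: Covalent radii (Å), used for distance-based connectivity inference.
COVALENT_RADII = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "P": 1.07,
    "F": 0.57,
    "Cl": 1.02,
}

WATER_MOLAR_MASS = 18.0153  # g/mol


def kT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy RT in kcal·mol⁻¹ at the given temperature (K)."""
    return GAS_CONSTANT_KCAL * temperature
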