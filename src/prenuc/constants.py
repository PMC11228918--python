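"""Physical constants and the handful of unit conversions the package relies on.

Everything downstream (Stokes–Einstein sizing, CNT critical diameters,
pair energies) mixes unit systems that are conventional in their own
sub-fields (nm/µs for light scattering, mJ/m² for interfacial energies,
kJ/mol for molecular energetics).  All conversions are centralized here so
they can be tested for exactness in one place.
"""

#: Boltzmann constant, J/K (exact, SI 2019).
BOLTZMANN_J_PER_K = 1.380649e-23

#: Molar gas constant, J/(mol·K), at the precision conventional in the
#: nucleation literature.
GAS_CONSTANT_J_PER_MOL_K = 8.314

#: Avogadro constant, 1/mol (exact, SI 2019).
AVOGADRO_PER_MOL = 6.02214076e23

#: Electric conversion factor f = 1/(4π ε0) in kJ·nm/(mol·e²); the value
#: used throughout molecular-simulation force fields.
COULOMB_KJ_NM_PER_MOL_E2 = 138.935458


def mj_per_m2_to_j_per_m2(gamma_mj: float) -> float:
    """Interfacial energy: mJ/m² → J/m²."""
    return gamma_mj * 1e-3


def m_to_nm(x_m: float) -> float:
    return x_m * 1e9


def nm2_per_us_to_m2_per_s(d: float) -> float:
    """Translational diffusivity: nm²/µs → m²/s (factor exactly 1e-12)."""
    return d * 1e-12


def mpa_s_to_pa_s(eta: float) -> float:
    """Viscosity: mPa·s → Pa·s."""
    return eta * 1e-3
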