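"""Physical constants and unit conventions.

Internal unit system (GROMACS-like): length nm, time ps, mass amu,
energy kJ/mol, charge in elementary charges, temperature K.  In these
units 1 amu nm^2/ps^2 == 1 kJ/mol exactly, so masses, velocities and
energies combine without conversion factors.
"""

#: Boltzmann constant, kJ mol^-1 K^-1 (i.e. the molar gas constant).
KB = 0.00831446261815324

#: Coulomb prefactor e^2 / (4 pi eps_vac), kJ mol^-1 nm e^-2.
COULOMB = 138.935458

#: Avogadro's number, mol^-1.
N_AVOGADRO = 6.02214076e23

#: kJ per kcal (thermochemical calorie).
KJ_PER_KCAL = 4.184

#: Litres per cubic nanometre.
LITRE_PER_NM3 = 1e-24


def kt(temperature: float) -> float:
    """Thermal energy k_B T in kJ/mol at *temperature* (K)."""
    return KB * temperature
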