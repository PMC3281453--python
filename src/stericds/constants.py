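"""Physical constants and the package's internal unit system.

Internal units: length in Angstrom (A), mass in atomic mass units (amu),
energy in kcal/mol, time in femtoseconds (fs).  In this system

    1 amu * A^2 / fs^2  =  2390.0574 kcal/mol

so an acceleration obtained from a force in kcal/mol/A divided by a mass in
amu must be multiplied by ``ACCEL_PER_FORCE`` (= 1/2390.0574 A/fs^2) before it
enters the equations of motion.  Every unit conversion in the package goes
through this module; nothing else defines a conversion factor.
"""

# 1 amu * A^2/fs^2 expressed in kcal/mol  (1.66053906660e-27 kg * 1e10 m^2/s^2
# * Avogadro / 4184 J/kcal)
KCAL_PER_AMU_A2_FS2 = 2390.0573614
# acceleration (A/fs^2) per unit force-over-mass (kcal/mol/A/amu)
ACCEL_PER_FORCE = 1.0 / KCAL_PER_AMU_A2_FS2

# Boltzmann constant, kcal/mol/K
KB = 0.001987204259

# Coulomb prefactor, kcal*A/(mol*e^2)
COULOMB_CONSTANT = 332.06371

# average atomic masses, amu
ELEMENT_MASSES = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "Mg": 24.305, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "K": 39.098, "Ca": 40.078, "Br": 79.904,
    "I": 126.904, "At": 209.987,
}

# single-bond covalent radii, A (Cordero-style values)
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Na": 1.66, "Mg": 1.41, "Si": 1.11, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "K": 2.03, "Ca": 1.76, "Br": 1.20,
    "I": 1.39, "At": 1.50,
}

# elements that may donate/accept hydrogen bonds
HBOND_ELECTRONEGATIVE = ("N", "O", "F")
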