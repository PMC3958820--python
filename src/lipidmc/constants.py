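"""Physical constants and unit conversions.

Internal units: lengths in Å, energies in kcal/mol, angles in radians,
temperature in K, pressure in atm, masses in amu, charges in elementary
charges.  Conversions to SI appear only inside the entropy calculation.
"""

# Boltzmann constant, kcal/(mol K)
KB = 0.0019872041

# Coulomb prefactor: q_i q_j / r in e^2/Å -> kcal/mol
COULOMB = 332.0636

# 1 atm * 1 Å^3 expressed in kcal/mol  (101325 Pa * 1e-30 m^3 * N_A / 4184)
ATM_A3_TO_KCAL_MOL = 1.458397e-5

# SI values used by the Schlitter entropy (mass-weighted covariance in amu Å^2)
KB_SI = 1.380649e-23          # J/K
HBAR_SI = 1.054571817e-34     # J s
AMU_SI = 1.66053906660e-27    # kg
ANGSTROM_SI = 1.0e-10         # m
EULER = 2.718281828459045

# kcal/mol per J/mol
J_PER_MOL_TO_KCAL_PER_MOL = 1.0 / 4184.0
AVOGADRO = 6.02214076e23

# (kB T e^2 / hbar^2) * m * sigma^2 is dimensionless when T in K, m in amu,
# sigma^2 in Å^2, after multiplying by this factor.
SCHLITTER_PREFACTOR = KB_SI * EULER**2 * AMU_SI * ANGSTROM_SI**2 / HBAR_SI**2

# kB T <A> / Var(A) with areas in Å^2 gives kcal/(mol Å^2); convert to mN/m.
# 1 kcal/(mol Å^2) = 4184 J / (6.02214e23 * 1e-20 m^2) = 694.77 mJ/m^2 = 694.77 mN/m
KCAL_PER_MOL_A2_TO_MN_PER_M = 4184.0 / AVOGADRO / 1.0e-20 * 1.0e3
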