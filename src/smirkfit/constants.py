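"""Physical constants and unit conventions.

Internal units throughout the package: Å for lengths, kcal/mol for energies,
degrees for angles in files and reports (radians only inside energy kernels),
elementary charge for partial charges.  Angle and harmonic force constants are
stored in the SMIRNOFF convention E = (k/2)(x - x0)^2 with k per rad^2 / Å^2.
"""

# Coulomb's constant in kcal·Å/(mol·e²)
COULOMB_CONSTANT = 332.0637133

HARTREE_TO_KCALMOL = 627.509474

# Default AMBER-family 1-4 scale factors
SCALE_VDW_14 = 0.5
SCALE_ELEC_14 = 1.0 / 1.2
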