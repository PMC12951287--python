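"""Physical constants in the GROMACS unit system (nm, ps, kJ/mol, e, amu)."""

#: Coulomb prefactor f = 1/(4 pi eps0) in kJ mol^-1 nm e^-2
COULOMB_CONSTANT = 138.935458

#: elementary charge, C
ELEMENTARY_CHARGE = 1.602176634e-19

#: vacuum permittivity, F/m
VACUUM_PERMITTIVITY = 8.8541878128e-12

#: converts a charge density double-integrated over z (units e/nm, i.e.
#: [e/nm^3] * nm^2) into volts: (e -> C, nm -> m, divide by eps0)
POTENTIAL_E_PER_NM_TO_VOLT = ELEMENTARY_CHARGE / 1e-9 / VACUUM_PERMITTIVITY

#: MSD slope conversion: 1 nm^2/ps = 1e-14 cm^2 / 1e-12 s
NM2_PER_PS_TO_CM2_PER_S = 1e-2

#: inverse of the above, for generating walks from a D given in cm^2/s
CM2_PER_S_TO_NM2_PER_PS = 1e2
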