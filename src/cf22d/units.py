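"""Unit conversion constants.

All internal math is in Hartree atomic units.  Geometries on disk are in
angstrom (standard XYZ dialect); benchmark statistics are reported in
kcal/mol.
"""

BOHR_PER_ANGSTROM = 1.8897259886
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM
KCALMOL_PER_HARTREE = 627.509

#: Kinetic-energy-density convention: tau_sigma = 1/2 sum_i |grad psi_i,sigma|^2
#: (the Minnesota-family convention).  Set to 1.0 to drop the one-half.
TAU_CONVENTION_FACTOR = 0.5

#: Spin densities below this (bohr^-3) are treated as vacuum: every working
#: variable takes its rho -> 0 limit there.
DENSITY_FLOOR = 1e-30
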