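"""Physical constants and default model parameters.

Unit system: lengths in Å, energies in kJ/mol, temperatures in K.  Spring
constants are per-mole quantities (kJ/(Å²·mol)), so thermal energy enters as
R·T.  All node masses are equal (1 g/mol per node), which makes every
mean-square-fluctuation output independent of the mass; the mass is kept
explicit so that eigenfrequencies have their physical meaning.
"""

#: molar gas constant, kJ/(mol·K)
GAS_CONSTANT = 8.314462618e-3

#: Boltzmann constant, J/K (only used for documentation-level conversions)
BOLTZMANN = 1.3806488e-23

#: Avogadro's number, 1/mol
AVOGADRO = 6.02214129e23

#: uniform node mass, kg (1 g/mol for every node, atoms and C1' beads alike)
NODE_MASS_KG = 1.0e-3 / AVOGADRO

#: contact cutoff added to the sum of Van der Waals radii, Å
DEFAULT_CUTOFF = 2.0

#: default all-atom spring constant, kJ/(Å²·mol)
DEFAULT_CA = 1.29

#: default coarse-grained spring constant, kJ/(Å²·mol)
DEFAULT_CG = 7.7

#: default temperature for built (non-crystal) structures, K
DEFAULT_TEMPERATURE = 300.0

#: relative tolerance separating rigid-body (zero) modes from internal modes
DEFAULT_ZERO_TOL = 1e-8

#: outlier threshold in standard deviations for robust profile correlations
DEFAULT_OUTLIER_SIGMA = 2.5

#: Bondi Van der Waals radii, Å, for the elements occurring in nucleic acids
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80}
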