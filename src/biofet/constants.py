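"""Physical constants and unit-conversion factors used across the package."""

#: Vacuum permittivity, F/m (CODATA 2018).
EPS0 = 8.8541878128e-12

#: One debye in SI, C·m.
DEBYE_TO_CM = 3.33564e-30

#: Dipole conversion: 1 elementary charge × 1 Å in debye.
EA_TO_DEBYE = 4.80320

#: Boltzmann constant, J/K (exact, SI 2019).
KB = 1.380649e-23

#: Temperature at which the devices and simulations were held, K.
ROOM_TEMPERATURE_K = 297.0

#: Relative permittivity typical for a dry, densely packed protein layer.
DEFAULT_PROTEIN_EPS_R = 3.0

#: Default interfacial footprint of one protein dipole, nm².  Not a measured
#: quantity: it is the package default for the area of the outermost protein
#: portion facing the semiconductor channel, chosen so that the Helmholtz
#: dipole-layer expression with a 283 D dipole and eps_r = 3 reproduces a
#: ~23.7 V threshold-voltage shift.  Treat it as a configuration parameter.
DEFAULT_FOOTPRINT_NM2 = 1.50
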