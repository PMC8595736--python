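"""Physical constants and unit conversions.

Internal unit system (MD-native): mass in g/mol (= amu), length in nm,
time in ps, temperature in K.  With kB expressed in kJ mol^-1 K^-1, thermal
energies in kJ/mol coincide numerically with amu nm^2 ps^-2, so kB*T/M is a
squared velocity in nm^2/ps^2 without further factors.

Conversions to laboratory units (Pa s um for membrane friction, um^2/s for
diffusion coefficients) happen only at the API boundary.
"""

# Boltzmann constant, kJ mol^-1 K^-1
KB = 0.00831446

AVOGADRO = 6.02214076e23  # mol^-1

# Friction: internal unit is g mol^-1 ps^-1.
#   g/mol/ps -> kg/s:   1e-3 / AVOGADRO * 1e12
#   Pa s um = kg m^-1 s^-1 * 1e-6 m = 1e-6 kg/s
# so g/mol/ps -> Pa s um multiplies by 1e15 / AVOGADRO.
FRICTION_TO_PA_S_UM = 1e15 / AVOGADRO

# Diffusion coefficient: nm^2/ps -> um^2/s  (1e-6 um^2 per nm^2, 1e12 ps per s)
NM2_PER_PS_TO_UM2_PER_S = 1e6

# Convenience time conversions
PS_PER_NS = 1e3
PS_PER_US = 1e6
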