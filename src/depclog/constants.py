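"""Physical constants used throughout the package (SI units).

Values are kept to the precision conventionally quoted in the
microfluidics/DEP literature; all force and permittivity arithmetic in the
package goes through these names so the constants live in exactly one place.
"""

#: Vacuum permittivity, F/m.
VACUUM_PERMITTIVITY = 8.854e-12

#: Boltzmann constant, J/K.
BOLTZMANN = 1.38e-23

#: Elementary charge, C.
ELEMENTARY_CHARGE = 1.602e-19
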