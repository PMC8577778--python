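"""Physical constants used throughout the package (SI units)."""

import math

#: Speed of light in vacuum, m/s.
C0 = 2.99792458e8

#: Permittivity of free space, F/m.
EPS0 = 8.8541878128e-12

#: Permeability of free space, H/m (exact in the pre-2019 SI, ample here).
MU0 = 4.0e-7 * math.pi

#: Impedance of free space, Ohm.
ETA0 = math.sqrt(MU0 / EPS0)
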