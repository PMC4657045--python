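"""Unit constants and converters.

All internal computation is in SI (m, N, Pa, J).  The literature on
microtubule mechanics mixes μm, nm, MPa and pN freely, so boundary code
multiplies by these factors on the way in and divides on the way out.
"""

import math

# length
M = 1.0
MM = 1e-3
UM = 1e-6
NM = 1e-9

# pressure
PA = 1.0
MPA = 1e6

# force
N = 1.0
PN = 1e-12

# areal density
PER_M2 = 1.0
PER_UM2 = 1e12  # molecules/μm² expressed per m²

AVOGADRO = 6.02214076e23  # mol^-1

TWO_PI = 2.0 * math.pi


def to_si(value: float, unit: float) -> float:
    """Convert ``value`` expressed in ``unit`` (e.g. ``units.UM``) to SI."""
    return value * unit


def from_si(value: float, unit: float) -> float:
    """Express an SI ``value`` in ``unit`` (e.g. ``units.PN``)."""
    return value / unit
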