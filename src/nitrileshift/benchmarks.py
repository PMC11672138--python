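"""Reference benchmark numbers for nitrile HB blueshifts.

Published observed/modeled blueshift pairs for nitrile probes in a protein
host (o-cyanophenylalanine in photoactive yellow protein, PYP), in protic
solvents, and in metal-organic-framework (MOF) hosts with carboxylic-acid
donors.  Rigid HBs (protein interior, MOFs) are compared against the
geometric blueshift surface directly; fluctuating HBs (solvent-exposed
probe, free o-tolunitrile in water/methanol) against lineshape-simulated
apparent blueshifts, since motional narrowing roughly halves the geometric
value there.  All values in cm^-1.
"""

from __future__ import annotations

__all__ = [
    "F92_PEAK", "F92_VSE_ONLY", "F28_PEAK", "F28_VSE_ONLY",
    "F92_FIELD", "F28_FIELD",
    "OBSERVED_VS_MODELED", "RIGID_CONTACTS",
]

# PYP variant with a buried, rigid HB to a threonine hydroxyl:
# experimental peak and the Stark-only reference at its -78 MV/cm field.
F92_PEAK = 2241.3
F92_VSE_ONLY = 2215.5
F92_FIELD = -78.0

# Solvent-exposed PYP variant H-bonded to bulk water (-64.9 MV/cm).
F28_PEAK = 2230.9
F28_VSE_ONLY = 2219.1
F28_FIELD = -64.9

#: Rigid-HB contact geometries (label, d Å, theta deg) with their published
#: observed and surface-modeled blueshifts.
RIGID_CONTACTS = [
    ("PYP-F92", 2.93, 169.0, 25.8, 27.2),
    ("MOF-allylic-acid", 2.85, 168.0, 36.0, 31.8),
    ("MOF-benzoic-acid", 2.80, 148.0, 29.0, 28.2),
    ("MOF-isophthalic-acid", 2.79, 150.0, 33.0, 32.2),
]

#: Seven (observed, modeled-or-simulated) blueshift pairs: the four rigid
#: contacts above plus three fluctuating-HB cases whose modeled values are
#: lineshape-simulated apparent blueshifts.
OBSERVED_VS_MODELED = [
    ("PYP-F92", 25.8, 27.2),
    ("MOF-allylic-acid", 36.0, 31.8),
    ("MOF-benzoic-acid", 29.0, 28.2),
    ("MOF-isophthalic-acid", 33.0, 32.2),
    ("PYP-F28", 11.8, 13.6),
    ("oTN-water", 15.2, 14.5),
    ("oTN-methanol", 13.1, 12.7),
]
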