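import math

import numpy as np
import pytest

from nitrileshift import CANONICAL_BLUESHIFT, DEFAULT_VSE


@pytest.fixture(scope="session")
def blue():
    return CANONICAL_BLUESHIFT


@pytest.fixture(scope="session")
def vse():
    return DEFAULT_VSE


def nitrile_pdb(donor_d: float, donor_theta: float,
                occupancies=None) -> str:
    """PDB text: a three-atom nitrile fragment along +z plus one water O
    placed at exactly (d, theta) from the nitrile N.

    ``theta`` is the C-N...O angle at N (180 = collinear head-on).  With
    the nitrile C at the origin and N at +1.16 z, the donor sits in the
    x-z plane.  ``occupancies`` optionally adds altloc copies of the donor:
    a list of (altloc, occupancy, d, theta).
    """
    ang = math.radians(180.0 - donor_theta)
    ox = donor_d * math.sin(ang)
    oz = 1.16 + donor_d * math.cos(ang)
    lines = [
        "HETATM    1  C1  LIG A   1       0.000   0.000  -1.440"
        "  1.00  0.00           C",
        "HETATM    2  C2  LIG A   1       0.000   0.000   0.000"
        "  1.00  0.00           C",
        "HETATM    3  N1  LIG A   1       0.000   0.000   1.160"
        "  1.00  0.00           N",
    ]
    serial = 4
    if occupancies is None:
        lines.append(
            f"HETATM{serial:>5}  O   HOH A   2    {ox:8.3f}   0.000"
            f"{oz:8.3f}  1.00  0.00           O")
    else:
        for alt, occ, d_i, th_i in occupancies:
            a = math.radians(180.0 - th_i)
            x, z = d_i * math.sin(a), 1.16 + d_i * math.cos(a)
            lines.append(
                f"HETATM{serial:>5}  O  {alt}HOH A   2    {x:8.3f}   0.000"
                f"{z:8.3f}{occ:6.2f}  0.00           O")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def pdb_factory():
    return nitrile_pdb
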