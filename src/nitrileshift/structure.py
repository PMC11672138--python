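"""Hydrogen-bond geometry extraction from PDB structures.

Finds O/N heavy-atom donors around a nitrile probe and reports the
heavy-atom HB distance ``d`` (nitrile N to donor) and angle ``theta`` (the
C-N···donor angle at the nitrile N, 180 deg for a collinear head-on
contact) that the blueshift surface consumes.  Heavy atoms only: hydrogen positions in crystal structures are
rarely resolved and unreliable in constrained simulations.

Conventions: first model only; alternate locations resolved by highest
occupancy, ties alphabetically; atoms of the probe's own residue excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import gemmi

from .stark import HBGeometry

__all__ = ["ProbeSelection", "StructureContact", "extract_hb_geometry",
           "find_nitriles"]


@dataclass(frozen=True)
class ProbeSelection:
    """Address of one C#N pair inside a structure.

    ``chain``/``resseq`` select the residue; ``carbon``/``nitrogen`` the
    atom names of the nitrile carbon and nitrogen.
    """

    chain: str
    resseq: int
    carbon: str
    nitrogen: str


@dataclass(frozen=True)
class StructureContact:
    """One donor heavy atom near the probe, with its derived HB geometry."""

    geometry: HBGeometry
    donor_chain: str
    donor_resname: str
    donor_resseq: int
    donor_atom: str
    donor_element: str
    probe_c: tuple[float, float, float]
    probe_n: tuple[float, float, float]
    donor_pos: tuple[float, float, float]


def _load(structure: Union[str, Path, gemmi.Structure]) -> gemmi.Structure:
    if isinstance(structure, gemmi.Structure):
        return structure
    path = Path(structure)
    if not path.exists():
        raise FileNotFoundError(f"no such structure file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except Exception as err:
        raise ValueError(f"malformed structure file {path}: {err}") from err
    if len(st) == 0 or all(len(chain) == 0 for chain in st[0]) \
            or len(st[0]) == 0:
        raise ValueError(f"structure {path} contains no model with atoms")
    return st


def _resolve_altloc(residue: gemmi.Residue, name: str) -> Optional[gemmi.Atom]:
    cands = [a for a in residue if a.name == name]
    if not cands:
        return None
    cands.sort(key=lambda a: (-a.occ, a.altloc))
    return cands[0]


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def extract_hb_geometry(structure: Union[str, Path, gemmi.Structure],
                        probe: ProbeSelection,
                        radius: float = 4.0) -> list[StructureContact]:
    """All O/N donor heavy atoms within ``radius`` Å of the nitrile N.

    Returns contacts sorted by distance, each carrying the validated
    :class:`~nitrileshift.stark.HBGeometry`.  Raises when the probe atoms
    cannot be found or the file does not parse.
    """
    st = _load(structure)
    model = st[0]

    probe_res = None
    for chain in model:
        if chain.name != probe.chain:
            continue
        for res in chain:
            if res.seqid.num == probe.resseq:
                probe_res = res
                break
    if probe_res is None:
        raise ValueError(
            f"probe residue {probe.chain}/{probe.resseq} not found")
    atom_c = _resolve_altloc(probe_res, probe.carbon)
    atom_n = _resolve_altloc(probe_res, probe.nitrogen)
    if atom_c is None or atom_n is None:
        raise ValueError(
            f"probe atoms {probe.carbon}/{probe.nitrogen} missing in "
            f"{probe.chain}/{probe.resseq}")
    pos_c = np.array([atom_c.pos.x, atom_c.pos.y, atom_c.pos.z])
    pos_n = np.array([atom_n.pos.x, atom_n.pos.y, atom_n.pos.z])
    nc = pos_c - pos_n   # theta is the C-N···donor angle at the nitrile N
    if np.linalg.norm(nc) < 1e-6:
        raise ValueError("degenerate C#N bond (coincident atoms)")

    contacts = []
    for chain in model:
        for res in chain:
            if (chain.name == probe.chain
                    and res.seqid.num == probe.resseq):
                continue
            seen: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.element.name not in ("N", "O"):
                    continue
                prev = seen.get(atom.name)
                if prev is None or (atom.occ, prev.altloc) > (prev.occ,
                                                              atom.altloc):
                    seen[atom.name] = atom
            for atom in seen.values():
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                d = float(np.linalg.norm(pos - pos_n))
                if d > radius or d < 1e-6:
                    continue
                theta = _angle_deg(nc, pos - pos_n)
                if theta <= 0:
                    theta = 1e-6
                contacts.append(StructureContact(
                    geometry=HBGeometry(d=d, theta=theta),
                    donor_chain=chain.name,
                    donor_resname=res.name,
                    donor_resseq=res.seqid.num,
                    donor_atom=atom.name,
                    donor_element=atom.element.name,
                    probe_c=tuple(pos_c), probe_n=tuple(pos_n),
                    donor_pos=tuple(pos)))
    contacts.sort(key=lambda c: c.geometry.d)
    return contacts


def find_nitriles(structure: Union[str, Path, gemmi.Structure],
                  bond_range: tuple[float, float] = (1.05, 1.25),
                  ) -> list[ProbeSelection]:
    """Heuristic scan for C#N pairs: C and N atoms of one residue separated
    by a triple-bond-like distance (default 1.05-1.25 Å)."""
    st = _load(structure)
    model = st[0]
    lo, hi = bond_range
    found = []
    for chain in model:
        for res in chain:
            carbons = [a for a in res if a.element.name == "C"]
            nitrogens = [a for a in res if a.element.name == "N"]
            for c in carbons:
                for n in nitrogens:
                    d = c.pos.dist(n.pos)
                    if lo <= d <= hi:
                        found.append(ProbeSelection(
                            chain=chain.name, resseq=res.seqid.num,
                            carbon=c.name, nitrogen=n.name))
    return found
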