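"""Labeled synthetic demonstration scenes.

Small hand-posed PDB scenes with known interaction content, built from the
same idealized group templates as :mod:`pistacks.fixtures`.  They exercise
multi-residue behaviour that single-pair fixtures cannot: ligand context
assignment, pi-chain assembly over mixed interaction types, and interface
scoping.  All coordinates are synthetic; none of these scenes is a real
crystal structure.
"""

from __future__ import annotations

import numpy as np

from .fixtures import (R5, SIDE5, SIDE6, _pdb_atom_line, regular_polygon)

#: bonding order of the Phe/Tyr ring used for idealized hexagons
_RING6 = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")

#: Trp hexagon in bonding order; the CD2-CE2 edge (vertices 0 and 5) carries
#: the fused pentagon
_TRP_HEX = ("CD2", "CE3", "CZ3", "CH2", "CZ2", "CE2")

#: purine hexagon in bonding order; C4-C5 (vertices 3 and 4) carry the
#: fused pentagon
_PURINE_HEX = ("N1", "C2", "N3", "C4", "C5", "C6")


def _fuse_pentagon(hex_coords: np.ndarray, i_a: int, i_b: int
                   ) -> list[np.ndarray]:
    """Three pentagon apex positions fused on the hexagon edge (i_a, i_b).

    The hexagon must lie in a plane parallel to z=0.  Returns the apex atoms
    ordered from the one bonded to vertex ``i_a`` to the one bonded to
    ``i_b``, placed on the far side of the edge from the hexagon center.
    """
    a, b = hex_coords[i_a], hex_coords[i_b]
    center = hex_coords.mean(axis=0)
    mid = 0.5 * (a + b)
    out_dir = mid - center
    out_dir = out_dir / np.linalg.norm(out_dir)
    half_edge = 0.5 * np.linalg.norm(b - a)
    pent_center = mid + np.sqrt(max(R5**2 - half_edge**2, 0.0)) * out_dir

    def rot_z(vec, ang):
        c, s = np.cos(ang), np.sin(ang)
        return np.array([c * vec[0] - s * vec[1],
                         s * vec[0] + c * vec[1], vec[2]])

    v_a = a - pent_center
    step = 2 * np.pi / 5
    sign = 1.0 if np.cross(v_a, b - pent_center)[2] > 0 else -1.0
    return [pent_center + rot_z(v_a, -sign * step * k) for k in (1, 2, 3)]


def ideal_ring6(center, phase_deg: float = 0.0):
    """Idealized Phe/Tyr ring: names, elements, coordinates."""
    coords = regular_polygon(6, SIDE6, phase_deg) + np.asarray(center, float)
    return list(_RING6), ["C"] * 6, coords


def ideal_trp(center, phase_deg: float = 0.0):
    """Idealized Trp aromatic system (fused 6-ring + 5-ring)."""
    hexagon = regular_polygon(6, SIDE6, phase_deg) + np.asarray(center, float)
    cg, cd1, ne1 = _fuse_pentagon(hexagon, 0, 5)
    names = list(_TRP_HEX) + ["CG", "CD1", "NE1"]
    elems = ["C"] * 6 + ["C", "C", "N"]
    coords = np.vstack([hexagon, cg, cd1, ne1])
    return names, elems, coords


def ideal_adenine(center, phase_deg: float = 0.0):
    """Idealized adenine ring system (purine atom names, 9 atoms)."""
    hexagon = regular_polygon(6, SIDE6, phase_deg) + np.asarray(center, float)
    n9, c8, n7 = _fuse_pentagon(hexagon, 3, 4)
    names = list(_PURINE_HEX) + ["N9", "C8", "N7"]
    elems = ["N", "C", "N", "C", "C", "C"] + ["N", "C", "N"]
    coords = np.vstack([hexagon, n9, c8, n7])
    return names, elems, coords


class _Builder:
    def __init__(self):
        self.lines: list[str] = []
        self.serial = 1

    def add(self, resname, chain, seq, names, elems, coords, het=False):
        for name, elem, xyz in zip(names, elems, coords):
            self.lines.append(_pdb_atom_line(self.serial, name, elem,
                                             resname, chain, seq, xyz,
                                             het=het))
            self.serial += 1

    def ter(self):
        self.lines.append("TER")

    def text(self) -> str:
        return "\n".join(self.lines + ["END"]) + "\n"


def ligand_scene() -> str:
    """An adenine-carrying ligand flanked by a Met and a Phe.

    Content (synthetic, by construction):
      * sulfur-pi: Met A1 SD 4.2 A above the adenine hexagon, shifted toward
        the N1 vertex so the closest-atom choice is unambiguous;
      * pi-pi: Phe A2 ring stacked 3.4 A below the adenine hexagon;
      * both records carry context=protein_ligand (ATP is a HETATM residue
        recognised through the nucleobase ligand template registry).
    """
    b = _Builder()
    sd = np.array([0.5, 0.0, 4.2])
    met = np.vstack([sd, sd + [1.5, 0.0, 0.8], sd + [-1.5, 0.0, 0.8]])
    b.add("MET", "A", 1, ["SD", "CG", "CE"], ["S", "C", "C"], met)
    names, elems, coords = ideal_ring6([0.0, 0.0, -3.4])
    b.add("PHE", "A", 2, names, elems, coords)
    b.ter()
    names, elems, coords = ideal_adenine([0.0, 0.0, 0.0])
    b.add("ATP", "B", 1, names, elems, coords, het=True)
    b.ter()
    return b.text()


def pi_chain_scene() -> str:
    """A nine-residue tower forming one pi-chain with a mixed tally.

    A single stack along z: four Phe rings (3 pi-pi edges), a Lys ammonium
    sandwiched between rings 4 and 6 (2 cation-pi edges), then two Met
    sulfurs alternating with rings (3 sulfur-pi edges).  Expected: one
    pi-chain with 9 members, 8 edges and type counts
    {pi_pi: 3, cation_pi: 2, sulfur_pi: 3}.
    """
    b = _Builder()
    z = 0.0
    for seq in (1, 2, 3, 4):
        names, elems, coords = ideal_ring6([0.0, 0.0, z])
        b.add("PHE", "A", seq, names, elems, coords)
        z += 3.8
    # ring 4 sits at z=11.4; the ammonium hovers between rings 4 and 6
    nz = np.array([0.0, 0.0, 14.9])
    b.add("LYS", "A", 5, ["NZ", "CE"], ["N", "C"],
          np.vstack([nz, nz + [1.5, 0.0, 0.0]]))
    names, elems, coords = ideal_ring6([0.0, 0.0, 18.4])
    b.add("PHE", "A", 6, names, elems, coords)
    sd = np.array([0.0, 0.0, 22.4])
    b.add("MET", "A", 7, ["SD", "CG", "CE"], ["S", "C", "C"],
          np.vstack([sd, sd + [1.5, 0.0, 0.8], sd + [-1.5, 0.0, 0.8]]))
    names, elems, coords = ideal_ring6([0.0, 0.0, 26.4])
    b.add("PHE", "A", 8, names, elems, coords)
    sd = np.array([0.0, 0.0, 30.4])
    b.add("MET", "A", 9, ["SD", "CG", "CE"], ["S", "C", "C"],
          np.vstack([sd, sd + [1.5, 0.0, 0.8], sd + [-1.5, 0.0, 0.8]]))
    b.ter()
    return b.text()


def interface_scene() -> str:
    """Two interaction pairs across a two-chain interface.

    Chain H holds a Tyr and a Phe; chain Y holds a Lys and a Trp, 50 A
    apart so the two pairs stay independent.  Expected under interface
    scope {H} vs {Y}: one cation-pi (Tyr H30 x Lys Y97) and one pi-pi
    (Phe H53 x Trp Y62), both context=interface, and no pi-chain (each
    component has a single edge).
    """
    b = _Builder()
    names, elems, coords = ideal_ring6([0.0, 0.0, 0.0])
    b.add("TYR", "H", 30, names, elems, coords)
    names, elems, coords = ideal_ring6([50.0, 0.0, 0.0])
    b.add("PHE", "H", 53, names, elems, coords)
    b.ter()
    nz = np.array([0.0, 0.0, 3.5])
    b.add("LYS", "Y", 97, ["NZ", "CE"], ["N", "C"],
          np.vstack([nz, nz + [1.5, 0.0, 0.0]]))
    names, elems, coords = ideal_trp([50.0, 0.0, 3.4])
    b.add("TRP", "Y", 62, names, elems, coords)
    b.ter()
    return b.text()
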