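"""Hydrogen bonds for stair-motif detection.

The primary route is ingesting the ``.hb2`` fixed-width output of the
external HBPLUS program, which the user runs beforehand.  A built-in
geometric detector is provided as a clearly-labelled approximation (plain
donor-acceptor distance plus an optional D-H...A angle check when hydrogens
are present) so that stair detection works without the external tool; it
does not place hydrogens and is not an HBPLUS re-implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .model import Residue, Structure

logger = logging.getLogger(__name__)

ResidueId = tuple[str, int, str]


@dataclass(frozen=True)
class HBond:
    donor_residue: ResidueId
    donor_resname: str
    donor_atom: str
    acceptor_residue: ResidueId
    acceptor_resname: str
    acceptor_atom: str
    da_distance: float
    source: str = "hb2_file"       # "hb2_file" | "builtin"

    def __post_init__(self):
        if self.da_distance <= 0:
            raise ValueError("donor-acceptor distance must be positive")
        if (self.donor_residue, self.donor_atom) == (
                self.acceptor_residue, self.acceptor_atom):
            raise ValueError("donor and acceptor are the same atom")

    def links(self, rid1: ResidueId, rid2: ResidueId) -> bool:
        return {self.donor_residue, self.acceptor_residue} == {rid1, rid2}


def _parse_hb2_id(field: str) -> tuple[ResidueId, str]:
    """Decode the 9-character HBPLUS residue identifier 'cSSSSiRRR'."""
    chain = field[0]
    chain = "" if chain == "-" else chain
    seqnum = int(field[1:5])
    icode = field[5]
    icode = "" if icode == "-" else icode
    resname = field[6:9].strip()
    return (chain, seqnum, icode), resname


def parse_hb2(path: str | Path) -> list[HBond]:
    """Parse an HBPLUS .hb2 file; malformed lines are logged and skipped."""
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise IOError(f"cannot read hb2 file {path}: {exc}") from exc

    out: list[HBond] = []
    saw_record = False
    for lineno, line in enumerate(lines, 1):
        if len(line) < 33 or not line[1:5].strip().isdigit():
            continue  # header / blank / commentary
        try:
            donor_id, donor_res = _parse_hb2_id(line[0:9])
            donor_atom = line[10:14].strip()
            acceptor_id, acceptor_res = _parse_hb2_id(line[14:23])
            acceptor_atom = line[24:28].strip()
            da = float(line[28:33])
            if not donor_atom or not acceptor_atom:
                raise ValueError("empty atom name")
            out.append(HBond(donor_id, donor_res, donor_atom,
                             acceptor_id, acceptor_res, acceptor_atom, da))
            saw_record = True
        except (ValueError, IndexError) as exc:
            logger.warning("%s:%d: malformed hb2 record skipped (%s)",
                           path, lineno, exc)
    if not saw_record:
        logger.warning("%s: no hydrogen-bond records parsed", path)
    return out


def write_hb2(hbonds: list[HBond], path: str | Path) -> None:
    """Write hydrogen bonds in the HBPLUS fixed-width record layout."""
    def fmt_id(rid: ResidueId, resname: str) -> str:
        chain = rid[0] or "-"
        icode = rid[2] or "-"
        return f"{chain[:1]}{rid[1]:04d}{icode[:1]}{resname:>3.3s}"

    lines = ["hb2 hydrogen-bond records (HBPLUS-compatible layout)"]
    for hb in hbonds:
        lines.append(
            f"{fmt_id(hb.donor_residue, hb.donor_resname)} "
            f"{hb.donor_atom:<4.4s}"
            f"{fmt_id(hb.acceptor_residue, hb.acceptor_resname)} "
            f"{hb.acceptor_atom:<4.4s}"
            f"{hb.da_distance:5.2f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# donor / acceptor heavy-atom tables (side chains, backbone, nucleobases)
_BACKBONE_DONOR = "N"
_BACKBONE_ACCEPTORS = ("O", "OXT")
_SIDECHAIN_DONORS = {
    "ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",), "ASN": ("ND2",), "GLN": ("NE2",), "SER": ("OG",),
    "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"), "MET": ("SD",),
}
_BASE_DONORS = {
    "DA": ("N6",), "A": ("N6",), "DG": ("N1", "N2"), "G": ("N1", "N2"),
    "DC": ("N4",), "C": ("N4",), "DT": ("N3",), "U": ("N3",),
}
_BASE_ACCEPTORS = {
    "DA": ("N1", "N3", "N7"), "A": ("N1", "N3", "N7"),
    "DG": ("O6", "N3", "N7"), "G": ("O6", "N3", "N7"),
    "DC": ("O2", "N3"), "C": ("O2", "N3"),
    "DT": ("O2", "O4"), "U": ("O2", "O4"),
}
_NA_BACKBONE_ACCEPTORS = ("OP1", "OP2", "O1P", "O2P", "O3'", "O4'", "O5'", "O2'")


def _donor_atoms(res: Residue) -> list[str]:
    names = []
    if res.entity_kind.value == "amino_acid":
        if res.resname != "PRO" and res.atom(_BACKBONE_DONOR):
            names.append(_BACKBONE_DONOR)
        names += [n for n in _SIDECHAIN_DONORS.get(res.resname, ())
                  if res.atom(n)]
    elif res.entity_kind.is_nucleotide:
        names += [n for n in _BASE_DONORS.get(res.resname, ()) if res.atom(n)]
    return names


def _acceptor_atoms(res: Residue) -> list[str]:
    names = []
    if res.entity_kind.value == "amino_acid":
        names += [n for n in _BACKBONE_ACCEPTORS if res.atom(n)]
        names += [n for n in _SIDECHAIN_ACCEPTORS.get(res.resname, ())
                  if res.atom(n)]
    elif res.entity_kind.is_nucleotide:
        names += [n for n in _BASE_ACCEPTORS.get(res.resname, ())
                  if res.atom(n)]
        names += [n for n in _NA_BACKBONE_ACCEPTORS if res.atom(n)]
    return names


def detect_hbonds_builtin(s: Structure, da_max: float = 3.5,
                          dha_min_deg: float = 90.0) -> list[HBond]:
    """Geometric donor-acceptor detection from a shipped atom table.

    A pair qualifies when the heavy-atom D-A distance is at most ``da_max``
    and, whenever the donor carries an explicit hydrogen, some D-H...A angle
    is at least ``dha_min_deg``.  Results are deterministic and independent
    of input atom order.
    """
    donors: list[tuple[Residue, str]] = []
    acceptors: list[tuple[Residue, str]] = []
    for res in s.residues():
        donors += [(res, n) for n in _donor_atoms(res)]
        acceptors += [(res, n) for n in _acceptor_atoms(res)]
    if not donors or not acceptors:
        return []

    acc_coords = np.vstack([r.atom(n).coord for r, n in acceptors])
    tree = cKDTree(acc_coords)
    out: list[HBond] = []
    for res_d, name_d in donors:
        d_atom = res_d.atom(name_d)
        hydrogens = [a for a in res_d.atoms
                     if a.is_hydrogen
                     and np.linalg.norm(a.coord - d_atom.coord) < 1.3]
        for j in tree.query_ball_point(d_atom.coord, da_max):
            res_a, name_a = acceptors[j]
            if res_a.id == res_d.id:
                continue
            a_atom = res_a.atom(name_a)
            da = float(np.linalg.norm(a_atom.coord - d_atom.coord))
            if da < 1e-6:
                continue
            if hydrogens:
                ok = False
                for h in hydrogens:
                    v1 = d_atom.coord - h.coord
                    v2 = a_atom.coord - h.coord
                    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if np.degrees(np.arccos(np.clip(c, -1, 1))) >= dha_min_deg:
                        ok = True
                        break
                if not ok:
                    continue
            out.append(HBond(res_d.id, res_d.resname, name_d,
                             res_a.id, res_a.resname, name_a,
                             round(da, 3), source="builtin"))
    out.sort(key=lambda hb: (hb.donor_residue, hb.donor_atom,
                             hb.acceptor_residue, hb.acceptor_atom))
    return out
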