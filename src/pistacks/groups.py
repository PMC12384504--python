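"""Extraction of interacting functional groups and their plane geometry.

Each residue contributes zero or more functional groups: aromatic ring
systems (Phe, Tyr, Trp, His, nucleobases, registered ligands), cationic
groups (Arg guanidinium, Lys ammonium, the His ND1/CE1/NE2 triad), planar
side-chain amides (Asn, Gln) and sulfur atoms (Cys SG, Met SD).  Planar
groups carry a least-squares plane normal; rings additionally carry their
centroid and radius r (mean centroid-to-atom distance), on which the
acceptance-cylinder radius rmax is based.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np

from . import registry
from .model import EntityKind, Residue

logger = logging.getLogger(__name__)


class GroupKind(enum.Enum):
    AROMATIC_RING = "aromatic_ring"
    CATION = "cation"
    AMIDE = "amide"
    SULFUR = "sulfur"


class GeometryError(ValueError):
    """Degenerate atom configuration (undefined plane or direction)."""


def plane_fit(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points; returns (centroid, unit normal).

    The normal is the singular vector of the centered coordinates with the
    smallest singular value; its sign is arbitrary and oriented downstream.
    For exactly three non-collinear points this is the exact plane.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise GeometryError("plane fit needs at least 3 atoms")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-8:  # rank < 2: collinear points, plane undefined
        raise GeometryError("collinear atoms: plane undefined")
    return centroid, vt[2] / np.linalg.norm(vt[2])


def ring_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Centroid, least-squares plane normal and radius of a 5/6-atom ring.

    The radius r is the mean centroid-to-atom distance, computed per ring
    instance so distorted rings get their actual size.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] not in (5, 6):
        raise GeometryError(f"ring must have 5 or 6 atoms, got {coords.shape[0]}")
    centroid, normal = plane_fit(coords)
    r = float(np.mean(np.linalg.norm(coords - centroid, axis=1)))
    return centroid, normal, r


@dataclass
class FunctionalGroup:
    kind: GroupKind
    parent: Residue
    atom_names: tuple[str, ...]
    coords: np.ndarray                       # (n, 3) in atom_names order
    planar: bool = False
    ring_size: int | None = None             # 5 | 6 for aromatic rings
    centroid: np.ndarray | None = None
    normal: np.ndarray | None = None         # unit vector, sign arbitrary
    ring_radius: float | None = None         # r, Angstrom

    @property
    def label(self) -> str:
        return f"{self.parent.label}/{self.kind.value}"

    def plane_normal(self) -> np.ndarray:
        if not self.planar:
            raise GeometryError(f"{self.label} is not planar")
        assert self.normal is not None
        return self.normal


@dataclass
class AromaticSystem:
    """One aromatic moiety: a single ring, or two fused rings (Trp, purines).

    Fused rings share exactly the two bridging atoms named in the registry
    (Trp: CD2/CE2, purines: C4/C5).
    """

    parent: Residue
    rings: list[FunctionalGroup] = field(default_factory=list)

    @property
    def is_fused(self) -> bool:
        return len(self.rings) == 2

    @property
    def label(self) -> str:
        return f"{self.parent.label}/aromatic"

    def all_atom_names(self) -> list[str]:
        seen: list[str] = []
        for ring in self.rings:
            for name in ring.atom_names:
                if name not in seen:
                    seen.append(name)
        return seen

    def all_coords(self) -> np.ndarray:
        res = self.parent
        return np.vstack([res.atom(n).coord for n in self.all_atom_names()])


def _build_ring(res: Residue, ring_def: dict) -> FunctionalGroup | None:
    names = ring_def["atoms"]
    atoms = [res.atom(n) for n in names]
    if any(a is None for a in atoms):
        missing = [n for n, a in zip(names, atoms) if a is None]
        logger.warning("%s: ring atoms missing %s; group skipped",
                       res.label, missing)
        return None
    coords = np.vstack([a.coord for a in atoms])
    try:
        centroid, normal, r = ring_geometry(coords)
    except GeometryError as exc:
        logger.warning("%s: degenerate ring geometry (%s); group skipped",
                       res.label, exc)
        return None
    return FunctionalGroup(
        kind=GroupKind.AROMATIC_RING, parent=res,
        atom_names=tuple(names), coords=coords, planar=True,
        ring_size=ring_def["size"], centroid=centroid, normal=normal,
        ring_radius=r,
    )


def _build_system(res: Residue, system_def: dict) -> AromaticSystem | None:
    rings = []
    for ring_def in system_def["rings"]:
        ring = _build_ring(res, ring_def)
        if ring is None:
            return None
        rings.append(ring)
    return AromaticSystem(parent=res, rings=rings)


def _build_planar(res: Residue, kind: GroupKind, names: list[str]
                  ) -> FunctionalGroup | None:
    atoms = [res.atom(n) for n in names]
    if any(a is None for a in atoms):
        missing = [n for n, a in zip(names, atoms) if a is None]
        logger.warning("%s: %s atoms missing %s; group skipped",
                       res.label, kind.value, missing)
        return None
    coords = np.vstack([a.coord for a in atoms])
    try:
        centroid, normal = plane_fit(coords)
    except GeometryError as exc:
        logger.warning("%s: %s degenerate (%s); group skipped",
                       res.label, kind.value, exc)
        return None
    return FunctionalGroup(kind=kind, parent=res, atom_names=tuple(names),
                           coords=coords, planar=True, centroid=centroid,
                           normal=normal)


def extract_groups(res: Residue) -> list[FunctionalGroup | AromaticSystem]:
    """All functional groups of a residue, per the shipped registry.

    Groups with any required heavy atom missing are skipped with a warning
    rather than raising.  His contributes both its aromatic ring and the
    ND1/CE1/NE2 cation triad; which one engages in a given pair is decided
    by the detector's typing precedence.  The Lys ammonium group includes
    its hydrogens when the structure has them and degrades gracefully to
    {NZ, CE} otherwise.
    """
    out: list[FunctionalGroup | AromaticSystem] = []
    if res.entity_kind is EntityKind.AMINO_ACID:
        entry = registry.amino_acid_groups().get(res.resname)
    elif res.entity_kind.is_nucleotide:
        entry = registry.nucleobase_groups().get(res.resname)
    elif res.entity_kind is EntityKind.LIGAND:
        systems = registry.ligand_templates().get(res.resname, [])
        entry = {"rings": systems} if systems else None
    else:
        entry = None
    if not entry:
        return out

    for system_def in entry.get("rings", []):
        system = _build_system(res, system_def)
        if system is not None:
            out.append(system)

    cation = entry.get("cation")
    if cation:
        if cation["planar"]:
            g = _build_planar(res, GroupKind.CATION, cation["atoms"])
            if g is not None:
                out.append(g)
        else:
            names = list(cation["atoms"])
            atoms = [res.atom(n) for n in names]
            if any(a is None for a in atoms):
                missing = [n for n, a in zip(names, atoms) if a is None]
                logger.warning("%s: cation atoms missing %s; group skipped",
                               res.label, missing)
            else:
                for hname in cation.get("optional_hydrogens", []):
                    h = res.atom(hname)
                    if h is not None:
                        names.append(hname)
                        atoms.append(h)
                out.append(FunctionalGroup(
                    kind=GroupKind.CATION, parent=res,
                    atom_names=tuple(names),
                    coords=np.vstack([a.coord for a in atoms]),
                    planar=False,
                ))

    amide = entry.get("amide")
    if amide:
        g = _build_planar(res, GroupKind.AMIDE, amide["atoms"])
        if g is not None:
            out.append(g)

    sulfur = entry.get("sulfur")
    if sulfur:
        atom = res.atom(sulfur["atom"])
        if atom is None:
            logger.warning("%s: sulfur atom %s missing; group skipped",
                           res.label, sulfur["atom"])
        else:
            out.append(FunctionalGroup(
                kind=GroupKind.SULFUR, parent=res,
                atom_names=(sulfur["atom"],),
                coords=atom.coord.reshape(1, 3), planar=False,
            ))
    return out
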