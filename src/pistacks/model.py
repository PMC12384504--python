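"""Light-weight structural model: atoms, residues, chains, detection scope.

PDB files are read with :mod:`gemmi` and converted to plain dataclasses so
that the geometric layers can operate on bare numpy arrays.  Only the first
MODEL of a file is used (crystal structures are the target domain), waters
are dropped, and alternate locations are resolved to a single conformer.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .registry import ligand_ring_codes, ligand_template_matches

logger = logging.getLogger(__name__)

#: 3-letter codes of the standard amino acids (selenomethionine included;
#: it is mapped onto Met when ``map_mse`` is enabled).
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",
}
DEOXYRIBONUCLEOTIDES = {"DA", "DG", "DC", "DT"}
RIBONUCLEOTIDES = {"A", "G", "C", "U"}
WATER_NAMES = {"HOH", "WAT", "DOD"}


class EntityKind(enum.Enum):
    AMINO_ACID = "amino_acid"
    DEOXYRIBONUCLEOTIDE = "deoxyribonucleotide"
    RIBONUCLEOTIDE = "ribonucleotide"
    LIGAND = "ligand"
    OTHER = "other"

    @property
    def is_nucleotide(self) -> bool:
        return self in (EntityKind.DEOXYRIBONUCLEOTIDE, EntityKind.RIBONUCLEOTIDE)


class AltlocPolicy(enum.Enum):
    """How alternate locations are collapsed to one conformer per atom."""

    OCCUPANCY = "occupancy"  # highest occupancy; ties -> 'A', then lexicographic
    FIRST = "first"          # first altloc encountered in file order


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seqnum: int
    icode: str
    resname: str
    atoms: list[Atom] = field(default_factory=list)
    entity_kind: EntityKind = EntityKind.OTHER

    @property
    def id(self) -> tuple[str, int, str]:
        """PDB author identifier (chain, seqnum, insertion code)."""
        return (self.chain_id, self.seqnum, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.resname}{self.seqnum}{self.icode}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_names(self) -> frozenset[str]:
        return frozenset(a.name for a in self.atoms)

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coord for a in self.atoms if not a.is_hydrogen]
        if not coords:
            return np.empty((0, 3))
        return np.vstack(coords)


@dataclass
class Scope:
    """Which residue pairs are examined for interactions.

    ``all_intra`` considers every residue pair in the structure; ``interface``
    restricts detection to pairs whose members belong to different chain
    groups (e.g. antibody chains vs antigen chain, or protein vs DNA).
    """

    kind: str = "all_intra"                      # "all_intra" | "interface"
    groups: tuple[frozenset[str], ...] = ()

    @staticmethod
    def intra() -> "Scope":
        return Scope("all_intra")

    @staticmethod
    def interface(*groups: Iterable[str]) -> "Scope":
        gs = tuple(frozenset(g) for g in groups)
        if len(gs) < 2:
            raise ValueError("interface scope needs at least two chain groups")
        seen: set[str] = set()
        for g in gs:
            if g & seen:
                raise ValueError("interface chain groups must be disjoint")
            seen |= g
        return Scope("interface", gs)

    def group_of(self, chain_id: str) -> int | None:
        for i, g in enumerate(self.groups):
            if chain_id in g:
                return i
        return None


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    scope: Scope = field(default_factory=Scope.intra)

    def residues(self) -> Iterator[Residue]:
        for chain_id in self.chains:
            yield from self.chains[chain_id]

    def residue(self, rid: tuple[str, int, str]) -> Residue | None:
        for res in self.chains.get(rid[0], []):
            if res.seqnum == rid[1] and res.icode == rid[2]:
                return res
        return None

    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    def validate_scope(self) -> None:
        if self.scope.kind == "interface":
            known = set(self.chains)
            for g in self.scope.groups:
                missing = g - known
                if missing:
                    raise ScopeError(
                        f"scope references absent chain(s) {sorted(missing)}"
                    )


class StructureError(ValueError):
    """Unreadable or empty structure input."""


class ScopeError(ValueError):
    """Detection scope refers to chains not present in the structure."""


def classify_residue(resname: str, atom_names: Iterable[str],
                     map_mse: bool = True) -> EntityKind:
    """Classify a residue by name and atom content.

    Standard amino acids, DNA and RNA nucleotides are recognised by name;
    HETATM groups are recognised as nucleobase-carrying ligands when their
    atom names contain a registered purine/pyrimidine ring template.
    Everything else (waters, ions, unknown chemistry) falls through to
    ``other`` and is ignored by detection.
    """
    resname = resname.strip().upper()
    if not resname:
        raise ValueError("empty residue name")
    if resname in WATER_NAMES:
        return EntityKind.OTHER
    if resname in STANDARD_AA:
        if resname == "MSE" and not map_mse:
            return EntityKind.OTHER
        return EntityKind.AMINO_ACID
    if resname in DEOXYRIBONUCLEOTIDES:
        return EntityKind.DEOXYRIBONUCLEOTIDE
    if resname in RIBONUCLEOTIDES:
        return EntityKind.RIBONUCLEOTIDE
    if ligand_template_matches(resname, frozenset(atom_names)):
        return EntityKind.LIGAND
    return EntityKind.OTHER


def _resolve_altlocs(atoms: list[Atom], policy: AltlocPolicy) -> list[Atom]:
    """Collapse alternate locations: one atom per atom name."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            by_name[a.name] = []
            order.append(a.name)
        by_name[a.name].append(a)
    out = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            out.append(group[0])
            continue
        if policy is AltlocPolicy.FIRST:
            out.append(group[0])
        else:
            # highest occupancy; ties prefer altloc 'A', then lexicographic
            def key(a: Atom):
                return (-a.occupancy, a.altloc != "A", a.altloc)
            out.append(sorted(group, key=key)[0])
    return out


def parse_pdb(path: str | Path,
              altloc_policy: AltlocPolicy = AltlocPolicy.OCCUPANCY,
              map_mse: bool = True) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Only the first MODEL is kept, waters are excluded, and alternate
    locations are resolved per ``altloc_policy`` (default: highest
    occupancy, ties broken toward altloc 'A').

    Raises
    ------
    StructureError
        If the file cannot be read or contains no atoms after filtering.
    """
    import gemmi

    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no coordinate model in {path}")
    model = st[0]

    out = Structure(id=path.stem)
    for chain in model:
        chain_id = chain.name or " "
        residues: list[Residue] = []
        for res in chain:
            resname = res.name.strip().upper()
            if resname in WATER_NAMES:
                continue
            atoms = []
            for at in res:
                atoms.append(Atom(
                    name=at.name.strip(),
                    element=at.element.name.upper(),
                    coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=float(at.occ),
                    altloc=at.altloc.strip() if at.altloc else "",
                    is_hetatm=res.het_flag == "H",
                ))
            if not atoms:
                continue
            atoms = _resolve_altlocs(atoms, altloc_policy)
            icode = res.seqid.icode.strip() if res.seqid.icode else ""
            r = Residue(
                chain_id=chain_id,
                seqnum=res.seqid.num,
                icode=icode,
                resname=resname,
                atoms=atoms,
            )
            r.entity_kind = classify_residue(resname, r.atom_names(), map_mse)
            residues.append(r)
        if residues:
            out.chains.setdefault(chain_id, []).extend(residues)

    if not any(out.residues()):
        raise StructureError(f"no atoms retained from {path}")
    return out


#: distance margin added to the global dmax when prefiltering residue pairs;
#: generous enough that no pair any criterion could accept is ever skipped
PREFILTER_MARGIN = 0.5


def iter_candidate_pairs(s: Structure, dmax_global: float = 6.0,
                         prefilter: bool = True,
                         min_seq_separation: int = 0,
                         ) -> Iterator[tuple[Residue, Residue]]:
    """Yield unordered residue pairs eligible for interaction detection.

    Residues classified ``other`` never appear.  With ``all_intra`` scope all
    distinct pairs are produced; with ``interface`` scope only pairs whose
    chains fall in different scope groups.  The KD-tree prefilter skips pairs
    whose closest heavy atoms are farther than ``dmax_global`` plus a safety
    margin; it can only remove pairs no distance criterion could accept.
    """
    s.validate_scope()
    residues = [r for r in s.residues() if r.entity_kind is not EntityKind.OTHER]

    def eligible(r1: Residue, r2: Residue) -> bool:
        if s.scope.kind == "interface":
            g1 = s.scope.group_of(r1.chain_id)
            g2 = s.scope.group_of(r2.chain_id)
            if g1 is None or g2 is None or g1 == g2:
                return False
        if (min_seq_separation > 0 and r1.chain_id == r2.chain_id
                and abs(r1.seqnum - r2.seqnum) < min_seq_separation):
            return False
        return True

    if not prefilter:
        for i in range(len(residues)):
            for j in range(i + 1, len(residues)):
                if eligible(residues[i], residues[j]):
                    yield residues[i], residues[j]
        return

    coords, owner = [], []
    for idx, r in enumerate(residues):
        hc = r.heavy_coords()
        coords.append(hc)
        owner.extend([idx] * len(hc))
    if not owner:
        return
    tree = cKDTree(np.vstack(coords))
    cutoff = dmax_global + PREFILTER_MARGIN
    close: set[tuple[int, int]] = set()
    for a, b in tree.query_pairs(r=cutoff):
        ia, ib = owner[a], owner[b]
        if ia != ib:
            close.add((min(ia, ib), max(ia, ib)))
    for ia, ib in sorted(close):
        if eligible(residues[ia], residues[ib]):
            yield residues[ia], residues[ib]
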