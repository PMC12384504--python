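"""Pairwise typing and validation of pi-involving interactions.

Five interaction classes are detected between functional groups: pi-pi
(aromatic x aromatic), cation-pi (aromatic x Arg/Lys), amino-pi (aromatic x
Asn/Gln amide), His-pi (His against another aromatic moiety) and sulfur-pi
(aromatic x Cys/Met sulfur).  A pair passes when the closest-atom distance
is within the class's dmax and the partner's closest atom falls inside the
acceptance cylinder of radius rmax = 2r (3r for pi-pi) on the aromatic ring.

Typing precedence: any aromatic-aromatic pair involving a His ring is typed
His-pi only (never doubly reported as pi-pi); Arg/Lys against a His ring is
typed cation-pi with His as the aromatic partner 1.  By convention partner 1
is always the aromatic moiety.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .geometry import PairGeometry, beta_angle, closest_atom_pair, cylinder_alpha, select_ring
from .groups import AromaticSystem, FunctionalGroup, GeometryError, GroupKind, extract_groups
from .model import EntityKind, Residue, Structure, iter_candidate_pairs

logger = logging.getLogger(__name__)


class InteractionType(enum.Enum):
    PI_PI = "pi_pi"
    CATION_PI = "cation_pi"
    AMINO_PI = "amino_pi"
    HIS_PI = "his_pi"
    SULFUR_PI = "sulfur_pi"


class Context(enum.Enum):
    INTRA = "intra"
    INTERFACE = "interface"
    PROTEIN_LIGAND = "protein_ligand"
    PROTEIN_NA = "protein_NA"
    BASE_BASE = "base_base"


@dataclass(frozen=True)
class Thresholds:
    """Distance caps and cylinder-radius multipliers, user-overridable."""

    dmax_pipi: float = 5.0           # Angstrom, pi-pi
    dmax_sulfur: float = 6.0         # Angstrom, sulfur-pi
    dmax_cat_amino_his: float = 4.5  # Angstrom, cation-, amino- and His-pi
    rmax_multiplier_pipi: float = 3.0
    rmax_multiplier_other: float = 2.0

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive")

    def dmax(self, itype: InteractionType) -> float:
        if itype is InteractionType.PI_PI:
            return self.dmax_pipi
        if itype is InteractionType.SULFUR_PI:
            return self.dmax_sulfur
        return self.dmax_cat_amino_his

    def rmax_multiplier(self, itype: InteractionType) -> float:
        if itype is InteractionType.PI_PI:
            return self.rmax_multiplier_pipi
        return self.rmax_multiplier_other

    def as_dict(self) -> dict[str, float]:
        return {
            "dmax_pipi": self.dmax_pipi,
            "dmax_sulfur": self.dmax_sulfur,
            "dmax_cat_amino_his": self.dmax_cat_amino_his,
            "rmax_multiplier_pipi": self.rmax_multiplier_pipi,
            "rmax_multiplier_other": self.rmax_multiplier_other,
        }

    @classmethod
    def from_file(cls, path) -> "Thresholds":
        data = yaml.safe_load(open(path)) or {}
        known = cls().as_dict()
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


@dataclass(frozen=True)
class PartnerRef:
    residue_id: tuple[str, int, str]
    resname: str
    group_kind: str
    ring_used: int | None = None


@dataclass
class InteractionRecord:
    itype: InteractionType
    partner1: PartnerRef             # always the aromatic moiety
    partner2: PartnerRef
    geometry: PairGeometry
    context: Context = Context.INTRA

    @property
    def residue_pair(self) -> frozenset:
        return frozenset((self.partner1.residue_id, self.partner2.residue_id))

    def sort_key(self):
        return (self.partner1.residue_id, self.partner2.residue_id,
                self.itype.value)


def _split_groups(res: Residue):
    aromatics, cations, amides, sulfurs = [], [], [], []
    for g in extract_groups(res):
        if isinstance(g, AromaticSystem):
            aromatics.append(g)
        elif g.kind is GroupKind.CATION:
            cations.append(g)
        elif g.kind is GroupKind.AMIDE:
            amides.append(g)
        elif g.kind is GroupKind.SULFUR:
            sulfurs.append(g)
    return aromatics, cations, amides, sulfurs


def _aromatic_vs_group(system: AromaticSystem, group: FunctionalGroup,
                       itype: InteractionType, th: Thresholds
                       ) -> InteractionRecord | None:
    """One aromatic system against a cation/amide/sulfur/His-triad group."""
    names1 = system.all_atom_names()
    coords1 = system.all_coords()
    names2 = list(group.atom_names)
    a1, a2, d, _, j2 = closest_atom_pair(coords1, names1, group.coords, names2)
    if d > th.dmax(itype):
        return None
    ring = select_ring(system, a1)
    rmax = th.rmax_multiplier(itype) * ring.ring_radius
    try:
        alpha, offset, passes = cylinder_alpha(
            ring.centroid, ring.normal, group.coords[j2], rmax)
    except GeometryError:
        return None
    if not passes:
        return None
    beta = None
    if group.planar:
        beta = beta_angle(ring.normal, group.plane_normal())
    geom = PairGeometry(d=d, atom_1=a1, atom_2=a2, alpha=alpha,
                        lateral_offset=offset, ring_used=ring.ring_size,
                        beta=beta)
    return InteractionRecord(
        itype=itype,
        partner1=PartnerRef(system.parent.id, system.parent.resname,
                            "aromatic_ring", ring.ring_size),
        partner2=PartnerRef(group.parent.id, group.parent.resname,
                            group.kind.value),
        geometry=geom,
    )


def _pi_pi(s1: AromaticSystem, s2: AromaticSystem, th: Thresholds
           ) -> InteractionRecord | None:
    """Symmetric pi-pi evaluation: the cylinder is built on each ring in
    turn, with A the closest atom of the other ring; the configuration with
    the smallest alpha is retained and decides acceptance."""
    names1, names2 = s1.all_atom_names(), s2.all_atom_names()
    coords1, coords2 = s1.all_coords(), s2.all_coords()
    a1, a2, d, i1, j2 = closest_atom_pair(coords1, names1, coords2, names2)
    if d > th.dmax_pipi:
        return None

    configs = []
    for sys_a, own_atom, partner_coord, sys_b, other_atom in (
            (s1, a1, coords2[j2], s2, a2),
            (s2, a2, coords1[i1], s1, a1)):
        ring = select_ring(sys_a, own_atom)
        rmax = th.rmax_multiplier_pipi * ring.ring_radius
        try:
            alpha, offset, passes = cylinder_alpha(
                ring.centroid, ring.normal, partner_coord, rmax)
        except GeometryError:
            continue
        configs.append((alpha, offset, passes, sys_a, ring, own_atom,
                        sys_b, other_atom))
    if not configs:
        return None
    alpha, offset, passes, sys_a, ring, own_atom, sys_b, other_atom = \
        min(configs, key=lambda c: c[0])
    if not passes:
        return None
    other_ring = select_ring(sys_b, other_atom)
    beta = beta_angle(ring.normal, other_ring.normal)
    geom = PairGeometry(d=d, atom_1=own_atom, atom_2=other_atom, alpha=alpha,
                        lateral_offset=offset, ring_used=ring.ring_size,
                        beta=beta)
    return InteractionRecord(
        itype=InteractionType.PI_PI,
        partner1=PartnerRef(sys_a.parent.id, sys_a.parent.resname,
                            "aromatic_ring", ring.ring_size),
        partner2=PartnerRef(sys_b.parent.id, sys_b.parent.resname,
                            "aromatic_ring", other_ring.ring_size),
        geometry=geom,
    )


def detect_pair(res1: Residue, res2: Residue,
                th: Thresholds | None = None) -> list[InteractionRecord]:
    """All pi interactions between two residues (order-independent)."""
    th = th or Thresholds()
    if res1.id == res2.id:
        return []
    # canonical order keeps outputs identical under argument swap
    if res2.id < res1.id:
        res1, res2 = res2, res1
    arom1, cat1, ami1, sul1 = _split_groups(res1)
    arom2, cat2, ami2, sul2 = _split_groups(res2)

    out: list[InteractionRecord] = []

    def his_triad(res: Residue, cats: list[FunctionalGroup]
                  ) -> FunctionalGroup | None:
        if res.resname != "HIS":
            return None
        return cats[0] if cats else None

    for sa in arom1:
        for sb in arom2:
            his_a = sa.parent.resname == "HIS"
            his_b = sb.parent.resname == "HIS"
            if not his_a and not his_b:
                rec = _pi_pi(sa, sb, th)
                if rec is not None:
                    out.append(rec)
            elif his_a != his_b:
                # His against another aromatic: the non-His ring is partner 1
                # and the His ND1/CE1/NE2 triad is partner 2
                if his_a:
                    aromatic, triad = sb, his_triad(res1, cat1)
                else:
                    aromatic, triad = sa, his_triad(res2, cat2)
                if triad is None:
                    logger.warning("%s: His triad unavailable; His-pi skipped",
                                   (res1 if his_a else res2).label)
                    continue
                rec = _aromatic_vs_group(aromatic, triad,
                                         InteractionType.HIS_PI, th)
                if rec is not None:
                    out.append(rec)
            else:
                # His-His: evaluate both orientations, keep the smaller alpha
                cands = []
                for aromatic, triad in ((sa, his_triad(res2, cat2)),
                                        (sb, his_triad(res1, cat1))):
                    if triad is None:
                        continue
                    rec = _aromatic_vs_group(aromatic, triad,
                                             InteractionType.HIS_PI, th)
                    if rec is not None:
                        cands.append(rec)
                if cands:
                    out.append(min(cands, key=lambda r: r.geometry.alpha))

    # cation-pi: Arg/Lys groups only (the His triad engages via His-pi)
    for systems, cations in ((arom1, cat2), (arom2, cat1)):
        for sa in systems:
            for c in cations:
                if c.parent.resname not in ("ARG", "LYS"):
                    continue
                rec = _aromatic_vs_group(sa, c, InteractionType.CATION_PI, th)
                if rec is not None:
                    out.append(rec)

    for systems, amides in ((arom1, ami2), (arom2, ami1)):
        for sa in systems:
            for g in amides:
                rec = _aromatic_vs_group(sa, g, InteractionType.AMINO_PI, th)
                if rec is not None:
                    out.append(rec)

    for systems, sulfurs in ((arom1, sul2), (arom2, sul1)):
        for sa in systems:
            for g in sulfurs:
                rec = _aromatic_vs_group(sa, g, InteractionType.SULFUR_PI, th)
                if rec is not None:
                    out.append(rec)

    out.sort(key=InteractionRecord.sort_key)
    return out


def _assign_context(rec: InteractionRecord, s: Structure) -> Context:
    r1 = s.residue(rec.partner1.residue_id)
    r2 = s.residue(rec.partner2.residue_id)
    kinds = {r1.entity_kind, r2.entity_kind}
    if kinds <= {EntityKind.DEOXYRIBONUCLEOTIDE, EntityKind.RIBONUCLEOTIDE}:
        return Context.BASE_BASE
    if EntityKind.LIGAND in kinds:
        return Context.PROTEIN_LIGAND
    if any(k.is_nucleotide for k in kinds):
        return Context.PROTEIN_NA
    if r1.chain_id != r2.chain_id:
        return Context.INTERFACE
    return Context.INTRA


def detect_all(s: Structure, th: Thresholds | None = None,
               prefilter: bool = True,
               min_seq_separation: int = 0) -> list[InteractionRecord]:
    """Run detection over every candidate pair of a structure.

    Records are returned in a deterministic order.  Base-base stacking
    records (nucleobase x nucleobase, pi-pi criteria) are emitted whatever
    the scope so the stair-motif assembler can use them; they carry
    ``context=base_base`` and must be excluded from protein-interaction
    statistics.
    """
    th = th or Thresholds()
    dmax_global = max(th.dmax_pipi, th.dmax_sulfur, th.dmax_cat_amino_his)
    out: list[InteractionRecord] = []
    seen_pairs: set[frozenset] = set()
    for r1, r2 in iter_candidate_pairs(s, dmax_global=dmax_global,
                                       prefilter=prefilter,
                                       min_seq_separation=min_seq_separation):
        if r1.entity_kind.is_nucleotide and r2.entity_kind.is_nucleotide:
            continue  # handled below, independent of scope
        for rec in detect_pair(r1, r2, th):
            rec.context = _assign_context(rec, s)
            out.append(rec)
        seen_pairs.add(frozenset((r1.id, r2.id)))

    # base stacking within/between nucleic chains, regardless of scope
    nucleic = [r for r in s.residues() if r.entity_kind.is_nucleotide]
    for i in range(len(nucleic)):
        for j in range(i + 1, len(nucleic)):
            r1, r2 = nucleic[i], nucleic[j]
            if prefilter:
                from scipy.spatial.distance import cdist
                c1, c2 = r1.heavy_coords(), r2.heavy_coords()
                if len(c1) and len(c2) and cdist(c1, c2).min() > dmax_global + 0.5:
                    continue
            for rec in detect_pair(r1, r2, th):
                if rec.itype is InteractionType.PI_PI:
                    rec.context = Context.BASE_BASE
                    out.append(rec)

    out.sort(key=InteractionRecord.sort_key)
    return out
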