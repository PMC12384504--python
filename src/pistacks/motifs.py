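"""Assembly of pi-chains and protein-DNA/RNA stair motifs.

A pi-chain is a connected network of at least two pi interactions sharing
residues (e.g. a cation sandwiched between two aromatic rings).  A stair
motif couples two consecutive stacked nucleobases (a base-base pi-pi edge)
with an amino acid that makes a cation-, amino- or His-pi interaction to one
base and a hydrogen bond to the next base along the stack.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from . import registry
from .detect import Context, InteractionRecord, InteractionType
from .hbonds import HBond
from .model import EntityKind, Structure

logger = logging.getLogger(__name__)

ResidueId = tuple[str, int, str]

_STAIR_PI_TYPES = (InteractionType.CATION_PI, InteractionType.AMINO_PI,
                   InteractionType.HIS_PI)


@dataclass
class PiChain:
    members: list[ResidueId]                 # deterministic traversal order
    edges: list[InteractionRecord]
    type_counts: Counter = field(default_factory=Counter)

    def __post_init__(self):
        if not self.type_counts:
            self.type_counts = Counter(e.itype.value for e in self.edges)


@dataclass
class StairMotif:
    base_i: ResidueId                        # base receiving the pi edge
    base_j: ResidueId                        # stack neighbour, H-bonded
    amino_acid: ResidueId
    pi_edge: InteractionRecord
    stack_edge: InteractionRecord
    hbond: HBond


def find_pi_chains(records: list[InteractionRecord]) -> list[PiChain]:
    """Connected components with >= 2 interaction edges.

    Residues are nodes and every non-base-base record is an edge; a single
    isolated interaction is not a chain.  Members are listed in breadth-first
    order from the lowest residue id, neighbours visited in sorted order, so
    output is deterministic.
    """
    g = nx.MultiGraph()
    for rec in records:
        if rec.context is Context.BASE_BASE:
            continue
        g.add_edge(rec.partner1.residue_id, rec.partner2.residue_id,
                   record=rec)
    chains: list[PiChain] = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_edges() < 2:
            continue
        start = min(comp)
        order = []
        visited = {start}
        queue = [start]
        while queue:
            node = queue.pop(0)
            order.append(node)
            for nb in sorted(sub.neighbors(node)):
                if nb not in visited:
                    visited.add(nb)
                    queue.append(nb)
        edges = sorted((data["record"] for _, _, data in sub.edges(data=True)),
                       key=InteractionRecord.sort_key)
        chains.append(PiChain(members=order, edges=edges))
    chains.sort(key=lambda c: c.members[0])
    return chains


def _base_atoms(resname: str) -> frozenset[str]:
    atoms = registry.base_atom_names(resname)
    return atoms if atoms is not None else frozenset()


def _hbond_to_base(hb: HBond, aa: ResidueId, base: ResidueId,
                   base_resname: str, base_atoms_only: bool) -> bool:
    if not hb.links(aa, base):
        return False
    if not base_atoms_only:
        return True
    base_atom = (hb.donor_atom if hb.donor_residue == base
                 else hb.acceptor_atom)
    return base_atom in _base_atoms(base_resname)


def find_stair_motifs(records: list[InteractionRecord],
                      hbonds: list[HBond], s: Structure,
                      base_atoms_only: bool = True,
                      ) -> list[StairMotif]:
    """Enumerate stair motifs.

    For every cation-/amino-/His-pi record linking an amino acid to a base
    ``base_i``, and every strand neighbour ``base_j`` (same chain, sequence
    numbers one apart) stacked on ``base_i`` via a base-base pi-pi record, a
    motif is emitted when a hydrogen bond connects the amino acid to
    ``base_j``.  By default the H-bond must land on a base atom (not sugar
    or phosphate), since the motif is defined on the base stack.
    """
    if not any(r.entity_kind.is_nucleotide for r in s.residues()):
        return []
    if not hbonds:
        logger.warning("no hydrogen bonds supplied; stair motifs need "
                       "H-bonds identified beforehand")
        return []

    stacks: dict[frozenset, InteractionRecord] = {}
    for rec in records:
        if rec.context is Context.BASE_BASE:
            stacks[rec.residue_pair] = rec

    motifs: list[StairMotif] = []
    seen: set[tuple] = set()
    for rec in records:
        if rec.itype not in _STAIR_PI_TYPES:
            continue
        r1 = s.residue(rec.partner1.residue_id)
        r2 = s.residue(rec.partner2.residue_id)
        if r1 is None or r2 is None:
            continue
        if r1.entity_kind.is_nucleotide and r2.entity_kind is EntityKind.AMINO_ACID:
            base_i, aa = r1, r2
        elif r2.entity_kind.is_nucleotide and r1.entity_kind is EntityKind.AMINO_ACID:
            base_i, aa = r2, r1
        else:
            continue
        for delta in (-1, 1):
            bj_id = (base_i.chain_id, base_i.seqnum + delta, "")
            base_j = s.residue(bj_id)
            if base_j is None or not base_j.entity_kind.is_nucleotide:
                continue
            stack = stacks.get(frozenset((base_i.id, base_j.id)))
            if stack is None:
                continue
            for hb in hbonds:
                if _hbond_to_base(hb, aa.id, base_j.id, base_j.resname,
                                  base_atoms_only):
                    key = (aa.id, base_i.id, base_j.id)
                    if key in seen:
                        break
                    seen.add(key)
                    motifs.append(StairMotif(
                        base_i=base_i.id, base_j=base_j.id,
                        amino_acid=aa.id, pi_edge=rec, stack_edge=stack,
                        hbond=hb))
                    break
    motifs.sort(key=lambda m: (m.amino_acid, m.base_i, m.base_j))
    return motifs
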