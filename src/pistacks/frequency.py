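"""Contact-normalised interaction frequencies and geometry distributions.

The denominator for relative frequencies is the number of residue pairs in
contact: at least one heavy side-chain atom from each residue within 5 A.
Side chains start at CB, so Gly contributes no contacts; for nucleotides
the "side chain" is the nucleobase.  Frequencies are reported as counts per
100 contacts.  Geometry distributions cover the closest-atom distance d and
the displacement variables (1 - cos alpha) and (1 - cos beta).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import registry
from .detect import Context, InteractionRecord, InteractionType
from .model import EntityKind, Residue, Structure

logger = logging.getLogger(__name__)

CONTACT_DISTANCE = 5.0          # Angstrom, heavy side-chain atoms
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def sidechain_coords(res: Residue) -> np.ndarray:
    """Heavy side-chain atom coordinates used for contact counting."""
    if res.entity_kind is EntityKind.AMINO_ACID:
        coords = [a.coord for a in res.atoms
                  if not a.is_hydrogen and a.name not in _BACKBONE]
    elif res.entity_kind.is_nucleotide:
        base = registry.base_atom_names(res.resname) or frozenset()
        coords = [a.coord for a in res.atoms if a.name in base]
    elif res.entity_kind is EntityKind.LIGAND:
        coords = [a.coord for a in res.atoms if not a.is_hydrogen]
    else:
        coords = []
    if not coords:
        return np.empty((0, 3))
    return np.vstack(coords)


def count_contacts(s: Structure, cutoff: float = CONTACT_DISTANCE) -> int:
    """Number of residue pairs with side-chain heavy atoms within ``cutoff``.

    The structure's scope applies: with ``all_intra`` every pair counts,
    with ``interface`` only pairs whose chains lie in different groups.
    """
    s.validate_scope()
    residues = [r for r in s.residues()
                if r.entity_kind is not EntityKind.OTHER]
    coords, owner = [], []
    for idx, r in enumerate(residues):
        sc = sidechain_coords(r)
        coords.append(sc)
        owner.extend([idx] * len(sc))
    if not owner:
        return 0
    tree = cKDTree(np.vstack(coords))
    pairs: set[tuple[int, int]] = set()
    for a, b in tree.query_pairs(r=cutoff):
        ia, ib = owner[a], owner[b]
        if ia != ib:
            pairs.add((min(ia, ib), max(ia, ib)))
    n = 0
    for ia, ib in pairs:
        r1, r2 = residues[ia], residues[ib]
        if s.scope.kind == "interface":
            g1 = s.scope.group_of(r1.chain_id)
            g2 = s.scope.group_of(r2.chain_id)
            if g1 is None or g2 is None or g1 == g2:
                continue
        n += 1
    return n


@dataclass
class FrequencyTable:
    """Per-structure counts and contact-normalised frequencies (x100)."""

    per_structure: pd.DataFrame      # rows: structure id; cols: itype counts + contacts
    frequencies: pd.DataFrame        # same layout, counts / contacts * 100
    mean: pd.Series = field(init=False)
    std: pd.Series = field(init=False)

    def __post_init__(self):
        self.mean = self.frequencies.mean()
        # ddof=0 keeps the single-structure case well-defined (std = 0)
        self.std = self.frequencies.std(ddof=0)


def _count_by_type(records: list[InteractionRecord]) -> dict[str, int]:
    counts = {t.value: 0 for t in InteractionType}
    for rec in records:
        if rec.context is Context.BASE_BASE:
            continue  # base stacking serves motif assembly, not statistics
        counts[rec.itype.value] += 1
    return counts


def relative_frequencies(
        per_structure: dict[str, tuple[list[InteractionRecord], int]],
) -> FrequencyTable:
    """Contact-normalised frequencies for a batch of structures.

    ``per_structure`` maps structure id to (records, contact count).
    Structures with zero contacts are skipped with a warning, matching the
    undefined 0/0 normalisation.
    """
    rows = {}
    for sid, (records, contacts) in per_structure.items():
        if contacts <= 0:
            logger.warning("%s: no contacts; structure skipped", sid)
            continue
        row = _count_by_type(records)
        row["contacts"] = contacts
        rows[sid] = row
    if not rows:
        raise ValueError("no structure with a positive contact count")
    counts = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    freq = counts.drop(columns="contacts").div(counts["contacts"], axis=0) * 100.0
    return FrequencyTable(per_structure=counts, frequencies=freq)


VARIABLES = ("d", "one_minus_cos_alpha", "one_minus_cos_beta")


def _variable_value(rec: InteractionRecord, variable: str) -> float | None:
    if variable == "d":
        return rec.geometry.d
    if variable == "one_minus_cos_alpha":
        return 1.0 - float(np.cos(np.radians(rec.geometry.alpha)))
    if variable == "one_minus_cos_beta":
        if rec.geometry.beta is None:
            return None
        return 1.0 - float(np.cos(np.radians(rec.geometry.beta)))
    raise ValueError(f"unknown variable {variable!r}")


@dataclass
class GeometryHistogram:
    variable: str
    bin_edges: np.ndarray
    densities: dict[str, np.ndarray]     # per itype, sums to 1 over bins
    counts: dict[str, np.ndarray]

    def mode(self, itype: str) -> float:
        """Center of the highest-density bin for one interaction type."""
        dens = self.densities[itype]
        k = int(np.argmax(dens))
        return float(0.5 * (self.bin_edges[k] + self.bin_edges[k + 1]))


def geometry_histograms(records: list[InteractionRecord], variable: str,
                        bins: np.ndarray | int = 25,
                        value_range: tuple[float, float] | None = None,
                        include_base_base: bool = False) -> GeometryHistogram:
    """Normalised per-type histogram of d, (1-cos alpha) or (1-cos beta).

    Records without the variable (beta is undefined for Lys cation-pi and
    sulfur-pi) are excluded from that histogram.
    """
    values: dict[str, list[float]] = {}
    for rec in records:
        if rec.context is Context.BASE_BASE and not include_base_base:
            continue
        v = _variable_value(rec, variable)
        if v is None:
            continue
        values.setdefault(rec.itype.value, []).append(v)
    if not values:
        raise ValueError(f"no record defines variable {variable!r}")

    if value_range is None:
        allv = np.concatenate([np.asarray(v) for v in values.values()])
        value_range = (float(allv.min()), float(allv.max()) + 1e-9)
    edges = (np.asarray(bins, dtype=float) if np.ndim(bins)
             else np.histogram_bin_edges([], bins=bins, range=value_range))
    densities, counts = {}, {}
    for itype, vals in values.items():
        c, _ = np.histogram(vals, bins=edges)
        counts[itype] = c
        densities[itype] = c / c.sum() if c.sum() else c.astype(float)
    return GeometryHistogram(variable=variable, bin_edges=edges,
                             densities=densities, counts=counts)


def plot_histograms(hist: GeometryHistogram, path) -> None:
    """Write one line plot per interaction type (optional matplotlib hook)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    fig, ax = plt.subplots(figsize=(6, 4))
    for itype, dens in sorted(hist.densities.items()):
        ax.plot(centers, dens, label=itype)
    ax.set_xlabel(hist.variable)
    ax.set_ylabel("frequency")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
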