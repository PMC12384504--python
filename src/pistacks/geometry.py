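"""The three geometric criteria: closest-atom distance d, the acceptance
cylinder (alpha angle), and the plane-parallelism angle beta.

The cylinder criterion asks whether the partner's closest atom A lies inside
an infinite-height cylinder erected on the aromatic ring: base centered on
the ring centroid C, radius rmax, axis along the ring normal.  Implemented
as a perpendicular-offset test (|CA| sin(alpha) <= rmax), which is exactly
cylinder membership but numerically stable; the equivalent distance-dependent
angle cap is alpha_max(d) = arcsin(rmax / |CA|) when |CA| > rmax, else 90 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .groups import AromaticSystem, FunctionalGroup, GeometryError


@dataclass
class PairGeometry:
    """Geometry of one detected interaction.

    ``atom_1``/``atom_2`` are the closest atoms of partner 1 (the aromatic
    moiety) and partner 2; ``alpha`` is the angle between the ring normal
    (oriented toward partner 2's closest atom) and the centroid-to-atom
    vector; ``beta`` is present only when both groups are planar.
    """

    d: float
    atom_1: str
    atom_2: str
    alpha: float                 # degrees, [0, 90]
    lateral_offset: float        # |CA| sin(alpha), Angstrom
    ring_used: int | None        # 5 | 6, ring of partner 1 the cylinder sat on
    beta: float | None = None    # degrees, [0, 90], or None


def closest_atom_pair(coords1: np.ndarray, names1: list[str],
                      coords2: np.ndarray, names2: list[str]
                      ) -> tuple[str, str, float, int, int]:
    """Minimum-distance atom pair between two groups.

    Ties are broken by (name1, name2) lexicographic order so outputs are
    deterministic.  Returns (name1, name2, d, index1, index2).
    """
    if len(coords1) == 0 or len(coords2) == 0:
        raise GeometryError("empty atom group")
    dm = cdist(coords1, coords2)
    dmin = dm.min()
    best = None
    for i, j in zip(*np.nonzero(dm <= dmin + 1e-12)):
        key = (names1[i], names2[j])
        if best is None or key < best[0]:
            best = (key, int(i), int(j))
    (n1, n2), i, j = best
    return n1, n2, float(dm[i, j]), i, j


def select_ring(system: AromaticSystem, own_closest_atom: str
                ) -> FunctionalGroup:
    """Pick the ring of a fused system on which to build the cylinder.

    The ring whose centroid is nearer to the system's own atom involved in
    the closest inter-group contact is used; an exact tie goes to the
    6-membered ring (larger pi surface, deterministic output).
    """
    if not system.is_fused:
        return system.rings[0]
    atom = system.parent.atom(own_closest_atom)
    if atom is None:
        raise GeometryError(
            f"{system.label}: atom {own_closest_atom} not in residue")
    dists = [float(np.linalg.norm(atom.coord - ring.centroid))
             for ring in system.rings]
    # registry orders the 6-ring first; <= therefore implements the tie-break
    order = sorted(range(len(system.rings)),
                   key=lambda k: (dists[k], system.rings[k].ring_size != 6))
    return system.rings[order[0]]


def cylinder_alpha(centroid: np.ndarray, normal: np.ndarray, a: np.ndarray,
                   rmax: float) -> tuple[float, float, bool]:
    """Alpha angle and cylinder membership for partner atom ``a``.

    The ring normal is oriented toward ``a`` so alpha is in [0, 90]; the
    lateral offset |CA| sin(alpha) is compared against ``rmax``.  An atom
    exactly in the ring plane has alpha = 90 deg and passes only when it is
    within rmax of the centroid.
    """
    v = np.asarray(a, dtype=float) - np.asarray(centroid, dtype=float)
    norm_v = float(np.linalg.norm(v))
    if norm_v < 1e-9:
        raise GeometryError("partner atom coincides with ring centroid")
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    cos_alpha = abs(float(np.dot(v, n))) / norm_v
    cos_alpha = min(1.0, cos_alpha)
    alpha = float(np.degrees(np.arccos(cos_alpha)))
    # perpendicular distance from a to the cylinder axis through the centroid
    offset = float(np.linalg.norm(v - np.dot(v, n) * n))
    return alpha, offset, offset <= rmax


def beta_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Smallest angle between two plane normals, folded into [0, 90] deg.

    0 deg means stacked (parallel planes), 90 deg a T-shaped arrangement.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    c = abs(float(np.dot(n1, n2))) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    return float(np.degrees(np.arccos(min(1.0, c))))
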