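"""Synthetic PDB fixtures: idealized functional-group pairs posed at
prescribed distance d, elevation-related angle alpha and plane angle beta,
plus stacked-nucleobase "ladder" scenes for stair-motif testing.

The generator writes valid PDB text and an analytic truth record computed
with plain numpy from the generated coordinates (not from the nominal
request), so detector tests compare against geometry that actually exists
on file.  Rings are regular polygons: C-C 1.39 A for 6-rings, 1.37 A sides
for 5-rings.  Requested poses that are geometrically unreachable (e.g. a
stacked multi-atom group whose designated contact atom cannot be the
closest one) raise :class:`FixtureSpecError` rather than emitting a
misleading file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import cdist

SIDE6 = 1.39          # A, hexagon side (aromatic C-C)
SIDE5 = 1.37          # A, pentagon side
R6 = SIDE6 / (2 * np.sin(np.pi / 6))       # hexagon circumradius == side
R5 = SIDE5 / (2 * np.sin(np.pi / 5))

DEFAULT_THRESHOLDS = {
    "pi_pi": (5.0, 3.0),
    "cation_pi": (4.5, 2.0),
    "amino_pi": (4.5, 2.0),
    "his_pi": (4.5, 2.0),
    "sulfur_pi": (6.0, 2.0),
}


class FixtureSpecError(ValueError):
    """Requested pose is incompatible with the group shapes."""


@dataclass
class FixtureSpec:
    pair_type: str                       # itype name
    target_d: float                      # A
    target_alpha: float | None = None    # degrees
    target_beta: float | None = None     # degrees; planar partners only
    lateral_offset: float | None = None  # A, alternative to alpha
    seed: int = 0
    jitter: float = 0.0                  # A, Gaussian coordinate noise
    variant: str | None = None           # cation fixtures: "LYS" | "ARG"

    def __post_init__(self):
        if self.pair_type not in DEFAULT_THRESHOLDS:
            raise FixtureSpecError(f"unknown pair type {self.pair_type!r}")
        if self.target_d <= 0:
            raise FixtureSpecError("target_d must be positive")
        if (self.target_alpha is None) == (self.lateral_offset is None):
            raise FixtureSpecError(
                "exactly one of target_alpha / lateral_offset is required")
        if self.target_alpha is not None and not 0 <= self.target_alpha <= 90:
            raise FixtureSpecError("target_alpha must be in [0, 90] degrees")
        planar2 = self.pair_type in ("pi_pi", "amino_pi", "his_pi") or (
            self.pair_type == "cation_pi" and (self.variant or "LYS") == "ARG")
        if self.target_beta is not None and not planar2:
            raise FixtureSpecError(
                f"beta undefined for {self.pair_type}/{self.variant}")
        if planar2 and self.target_beta is None:
            raise FixtureSpecError(
                f"{self.pair_type} with a planar partner needs target_beta")
        if self.target_beta is not None and not 0 <= self.target_beta <= 90:
            raise FixtureSpecError("target_beta must be in [0, 90] degrees")


@dataclass
class FixtureTruth:
    """Detector-convention geometry recomputed from generated coordinates."""

    itype: str
    expected_detected: bool
    d: float
    alpha: float                    # as the detector reports (min-alpha rule)
    lateral_offset: float
    beta: float | None
    exact: bool                     # realized pose == request within 1e-3
    dmax: float
    rmax: float
    requested: dict = field(default_factory=dict)


def regular_polygon(n: int, side: float, phase_deg: float = 0.0) -> np.ndarray:
    """Vertices of a regular n-gon in the z=0 plane, centered at origin."""
    radius = side / (2 * np.sin(np.pi / n))
    ang = np.radians(phase_deg) + 2 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.zeros(n)])


# ---------------------------------------------------------------------------
# partner-1 templates (ring plane z=0, centroid at origin)

#: hexagon vertex order follows ring bonding: CG-CD1-CE1-CZ-CE2-CD2
_PHE_RING = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
_PHE_ELEM = ("C",) * 6


def _partner1_phe(phase_deg: float = 15.0):
    coords = regular_polygon(6, SIDE6, phase_deg)
    return list(_PHE_RING), list(_PHE_ELEM), coords


# ---------------------------------------------------------------------------
# partner-2 templates

def _frame(u: np.ndarray, alpha: float, beta: float | None
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In-plane frame (n2, w, e2) for a planar partner-2 group.

    The free azimuth of the plane normal is used to tilt the group's
    non-contact atoms as far as possible away from partner 1 (maximising
    the component of the in-plane direction w along the approach vector u),
    which keeps the designated contact atom the closest one whenever the
    request is reachable.
    """
    a = np.radians(alpha)
    if beta is None:
        b = 0.0
    else:
        b = np.radians(beta)
    sa, ca, sb, cb = np.sin(a), np.cos(a), np.sin(b), np.cos(b)
    if sa * sb > 1e-12 and ca * cb <= sa * sb:
        cosphi = -ca * cb / (sa * sb)
        phi = np.arccos(np.clip(cosphi, -1.0, 1.0))
    else:
        phi = np.pi
    n2 = np.array([sb * np.cos(phi), sb * np.sin(phi), cb])
    u_in_plane = u - np.dot(u, n2) * n2
    if np.linalg.norm(u_in_plane) < 1e-9:
        x = np.array([1.0, 0.0, 0.0])
        u_in_plane = x - np.dot(x, n2) * n2
    w = u_in_plane / np.linalg.norm(u_in_plane)
    e2 = np.cross(n2, w)
    return n2, w, e2


def _planar_ring_at(contact: np.ndarray, w: np.ndarray, e2: np.ndarray,
                    n: int, side: float) -> np.ndarray:
    """Regular n-gon with one vertex at ``contact``, centroid displaced
    along +w; vertex k sits at angle k*360/n around the centroid."""
    radius = side / (2 * np.sin(np.pi / n))
    center = contact + radius * w
    ang = 2 * np.pi * np.arange(n) / n
    return (center[None, :]
            + radius * (np.cos(ang)[:, None] * (-w)[None, :]
                        + np.sin(ang)[:, None] * e2[None, :]))


def _partner2_template(spec: FixtureSpec, contact: np.ndarray,
                       u: np.ndarray):
    """Atom names, elements, coordinates and the detection-group subset for
    partner 2, given the contact-atom position."""
    beta = spec.target_beta
    alpha_nominal = spec.target_alpha if spec.target_alpha is not None else 45.0
    kind = spec.pair_type
    if kind == "pi_pi":
        _, w, e2 = _frame(u, alpha_nominal, beta)
        coords = _planar_ring_at(contact, w, e2, 6, SIDE6)
        names = list(_PHE_RING)
        return names, ["C"] * 6, coords, list(range(6)), "PHE"
    if kind == "his_pi":
        _, w, e2 = _frame(u, alpha_nominal, beta)
        coords = _planar_ring_at(contact, w, e2, 5, SIDE5)
        # ring bonding order starting at the contact vertex:
        # ND1 - CE1 - NE2 - CD2 - CG
        names = ["ND1", "CE1", "NE2", "CD2", "CG"]
        elems = ["N", "C", "N", "C", "C"]
        group_idx = [0, 1, 2]        # the ND1/CE1/NE2 cation triad
        return names, elems, coords, group_idx, "HIS"
    if kind == "amino_pi":
        _, w, e2 = _frame(u, alpha_nominal, beta)
        cg = contact + 1.33 * w
        od1 = cg + 1.23 * (np.cos(np.radians(58)) * w
                           + np.sin(np.radians(58)) * e2)
        coords = np.vstack([contact, cg, od1])
        return ["ND2", "CG", "OD1"], ["N", "C", "O"], coords, [0, 1, 2], "ASN"
    if kind == "cation_pi":
        variant = (spec.variant or "LYS").upper()
        if variant == "LYS":
            ce = contact + 1.5 * u
            coords = np.vstack([contact, ce])
            return ["NZ", "CE"], ["N", "C"], coords, [0, 1], "LYS"
        if variant == "ARG":
            _, w, e2 = _frame(u, alpha_nominal, beta)
            cz = contact + 1.33 * w
            nh2 = cz + 1.33 * (0.5 * w + np.sin(np.radians(60)) * e2)
            ne = cz + 1.33 * (0.5 * w - np.sin(np.radians(60)) * e2)
            coords = np.vstack([contact, nh2, cz, ne])
            return (["NH1", "NH2", "CZ", "NE"], ["N", "N", "C", "N"],
                    coords, [0, 1, 2, 3], "ARG")
        raise FixtureSpecError(f"unknown cation variant {variant!r}")
    if kind == "sulfur_pi":
        side = np.cross(u, [0.0, 1.0, 0.0])
        if np.linalg.norm(side) < 1e-9:
            side = np.cross(u, [1.0, 0.0, 0.0])
        side = side / np.linalg.norm(side)
        cg = contact + 1.8 * (u + 0.25 * side) / np.linalg.norm(u + 0.25 * side)
        ce = contact + 1.8 * (u - 0.25 * side) / np.linalg.norm(u - 0.25 * side)
        coords = np.vstack([contact, cg, ce])
        return ["SD", "CG", "CE"], ["S", "C", "C"], coords, [0], "MET"
    raise FixtureSpecError(f"unknown pair type {kind!r}")


def _closest_pair(c1: np.ndarray, names1: list[str],
                  c2: np.ndarray, names2: list[str]):
    dm = cdist(c1, c2)
    dmin = dm.min()
    best = None
    for i, j in zip(*np.nonzero(dm <= dmin + 1e-12)):
        key = (names1[i], names2[j])
        if best is None or key < best[0]:
            best = (key, int(i), int(j))
    _, i, j = best
    return i, j, float(dm[i, j])


def _alpha_offset(centroid, normal, a):
    v = np.asarray(a) - np.asarray(centroid)
    nv = np.linalg.norm(v)
    n = np.asarray(normal) / np.linalg.norm(normal)
    cos_a = min(1.0, abs(float(np.dot(v, n))) / nv)
    alpha = float(np.degrees(np.arccos(cos_a)))
    offset = float(np.linalg.norm(v - np.dot(v, n) * n))
    return alpha, offset


def _ring_descr(coords: np.ndarray):
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    r = float(np.mean(np.linalg.norm(centered, axis=1)))
    return centroid, normal, r


def _pdb_atom_line(serial: int, name: str, elem: str, resname: str,
                   chain: str, seqnum: int, xyz: np.ndarray,
                   het: bool = False) -> str:
    record = "HETATM" if het else "ATOM  "
    pad_name = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (f"{record}{serial:5d} {pad_name} {resname:>3s} {chain}"
            f"{seqnum:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {elem:>2s}")


def _truth_from_coords(spec: FixtureSpec, coords1, names1, coords2_group,
                       names2_group, contact_idx_in_group: int
                       ) -> FixtureTruth:
    """Recompute detector-convention geometry with plain numpy."""
    dmax, mult = DEFAULT_THRESHOLDS[spec.pair_type]
    i1, j2, d = _closest_pair(coords1, names1, coords2_group, names2_group)
    cen1, nrm1, r1 = _ring_descr(coords1)
    a_coord = coords2_group[j2]
    alpha1, off1 = _alpha_offset(cen1, nrm1, a_coord)
    rmax1 = mult * r1
    if spec.pair_type == "pi_pi":
        cen2, nrm2, r2 = _ring_descr(coords2_group)
        alpha2, off2 = _alpha_offset(cen2, nrm2, coords1[i1])
        rmax2 = mult * r2
        if alpha2 < alpha1:
            alpha, offset, rmax, passes = alpha2, off2, rmax2, off2 <= rmax2
        else:
            alpha, offset, rmax, passes = alpha1, off1, rmax1, off1 <= rmax1
        beta = _beta(nrm1, nrm2)
    else:
        alpha, offset, rmax, passes = alpha1, off1, rmax1, off1 <= rmax1
        beta = None
        if spec.target_beta is not None or spec.pair_type in (
                "amino_pi", "his_pi"):
            if spec.pair_type == "his_pi":
                plane = coords2_group[:3]
            else:
                plane = coords2_group
            if len(plane) >= 3:
                _, nrm2, _ = _ring_descr_any(plane)
                beta = _beta(nrm1, nrm2)
    detected = d <= dmax and passes
    req = {"d": spec.target_d, "alpha": spec.target_alpha,
           "beta": spec.target_beta, "lateral_offset": spec.lateral_offset}
    exact = (
        abs(d - spec.target_d) <= 1e-3
        and j2 == contact_idx_in_group
        and (spec.target_alpha is None or abs(alpha1 - spec.target_alpha) <= 1e-3)
        and (spec.lateral_offset is None
             or abs(off1 - spec.lateral_offset) <= 1e-3)
        and (spec.target_beta is None or beta is None
             or abs(beta - spec.target_beta) <= 1e-3)
        and (spec.pair_type != "pi_pi" or alpha == alpha1)
    )
    return FixtureTruth(
        itype=spec.pair_type, expected_detected=bool(detected), d=d,
        alpha=alpha, lateral_offset=offset, beta=beta, exact=bool(exact),
        dmax=dmax, rmax=rmax, requested=req)


def _ring_descr_any(coords: np.ndarray):
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2], 0.0


def _beta(n1, n2) -> float:
    c = abs(float(np.dot(n1, n2))) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    return float(np.degrees(np.arccos(min(1.0, c))))


def generate_pair_fixture(spec: FixtureSpec,
                          chain1: str = "A", chain2: str = "B",
                          strict: bool = True
                          ) -> tuple[str, FixtureTruth]:
    """PDB text for one idealized interacting pair, plus its truth record.

    Partner 1 is a regular aromatic ring at the origin in the z=0 plane
    (phase-rotated so no vertex lies on the x axis); partner 2 is posed so
    its designated contact atom realises the requested (d, alpha, beta).
    With ``strict`` (default), a pose whose realised geometry deviates from
    the request by more than 1e-3 raises :class:`FixtureSpecError`.
    """
    names1, elems1, coords1 = _partner1_phe()

    def build(alpha_deg: float):
        u = np.array([np.sin(np.radians(alpha_deg)), 0.0,
                      np.cos(np.radians(alpha_deg))])
        local = FixtureSpec(**{**spec.__dict__,
                               "target_alpha": alpha_deg,
                               "lateral_offset": None})

        def group_at(t: float):
            contact = t * u
            names2, elems2, coords2, gidx, resname2 = _partner2_template(
                local, contact, u)
            return names2, elems2, coords2, gidx, resname2

        def dist(t: float) -> float:
            _, _, coords2, gidx, _ = group_at(t)
            return float(cdist(coords1, coords2[gidx]).min())

        lo, hi = 0.3, spec.target_d + 12.0
        if dist(lo) > spec.target_d or dist(hi) < spec.target_d:
            raise FixtureSpecError(
                f"target d={spec.target_d} unreachable for {spec.pair_type} "
                f"at alpha={alpha_deg}")
        t_star = brentq(lambda t: dist(t) - spec.target_d, lo, hi,
                        xtol=1e-10)
        return group_at(t_star), u, t_star

    if spec.target_alpha is not None:
        (names2, elems2, coords2, gidx, resname2), u, _ = build(
            spec.target_alpha)
    else:
        # solve for the alpha realising the requested lateral offset
        def offset_of(alpha_deg: float) -> float:
            (n2s, e2s, c2, gi, _), _, _ = build(alpha_deg)
            cen1, nrm1, _ = _ring_descr(coords1)
            i1, j2, _ = _closest_pair(coords1, names1, c2[gi],
                                      [n2s[k] for k in gi])
            _, off = _alpha_offset(cen1, nrm1, c2[gi][j2])
            return off
        try:
            alpha_star = brentq(
                lambda a: offset_of(a) - spec.lateral_offset, 1e-6, 89.999,
                xtol=1e-9)
        except ValueError as exc:
            raise FixtureSpecError(
                f"lateral offset {spec.lateral_offset} unreachable") from exc
        (names2, elems2, coords2, gidx, resname2), u, _ = build(alpha_star)

    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        coords1 = coords1 + rng.normal(0.0, spec.jitter, coords1.shape)
        coords2 = coords2 + rng.normal(0.0, spec.jitter, coords2.shape)

    group_names = [names2[k] for k in gidx]
    exact_truth = _truth_from_coords(spec, coords1, names1, coords2[gidx],
                                     group_names, contact_idx_in_group=0)
    if strict and spec.jitter == 0 and not exact_truth.exact:
        raise FixtureSpecError(
            f"pose unreachable: realised (d={exact_truth.d:.3f}, "
            f"alpha={exact_truth.alpha:.2f}, beta={exact_truth.beta}) "
            f"deviates from request {exact_truth.requested}")

    # the truth record describes what is actually on file: PDB coordinates
    # carry 3 decimals, and near-threshold poses can flip on that rounding
    coords1 = np.round(coords1, 3)
    coords2 = np.round(coords2, 3)
    truth = _truth_from_coords(spec, coords1, names1, coords2[gidx],
                               group_names, contact_idx_in_group=0)
    truth.exact = exact_truth.exact

    lines = []
    serial = 1
    for name, elem, xyz in zip(names1, elems1, coords1):
        lines.append(_pdb_atom_line(serial, name, elem, "PHE", chain1, 1, xyz))
        serial += 1
    lines.append("TER")
    for name, elem, xyz in zip(names2, elems2, coords2):
        lines.append(_pdb_atom_line(serial, name, elem, resname2, chain2, 1,
                                    xyz))
        serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# stair-motif ladder

_PURINE_HEX = ("N1", "C2", "N3", "C4", "C5", "C6")
_PURINE_HEX_ELEM = ("N", "C", "N", "C", "C", "C")


def _ideal_guanine(center: np.ndarray, azimuth_deg: float
                   ) -> tuple[list[str], list[str], np.ndarray]:
    """Idealized guanine base in a plane parallel to z=0.

    Hexagon N1..C6 around ``center``; pentagon fused on the C4-C5 edge on
    the far side; exocyclic O6 on C6 and N2 on C2.
    """
    hexagon = regular_polygon(6, SIDE6, azimuth_deg)
    names = list(_PURINE_HEX)
    elems = list(_PURINE_HEX_ELEM)
    coords = [hexagon[i] for i in range(6)]
    c4, c5 = hexagon[3], hexagon[4]
    mid = 0.5 * (c4 + c5)
    out_dir = mid / np.linalg.norm(mid)          # away from hexagon center
    # pentagon on the C4-C5 edge: N9 bonded to C4, N7 to C5, C8 apex
    edge = c5 - c4
    edge_len = np.linalg.norm(edge)
    h_apex = np.sqrt(SIDE5**2 - (edge_len / 2) ** 2)  # apex-ish construction
    apo = SIDE5 / (2 * np.tan(np.pi / 5))
    pent_center = mid + np.sqrt(max(R5**2 - (edge_len / 2) ** 2, 0)) * out_dir
    # place remaining pentagon vertices by angle around its center
    def rot(vec, ang):
        c, s = np.cos(ang), np.sin(ang)
        return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1],
                         vec[2]])
    v4 = c4 - pent_center
    step = 2 * np.pi / 5
    sign = 1.0 if np.cross(v4, c5 - pent_center)[2] > 0 else -1.0
    n9 = pent_center + rot(v4, -sign * step)
    c8 = pent_center + rot(v4, -sign * 2 * step)
    n7 = pent_center + rot(v4, -sign * 3 * step)
    for nm, el, xyz in (("N7", "N", n7), ("C8", "C", c8), ("N9", "N", n9)):
        names.append(nm)
        elems.append(el)
        coords.append(xyz)
    c6, c2v = hexagon[5], hexagon[1]
    o6 = c6 + 1.23 * (c6 / np.linalg.norm(c6))
    n2 = c2v + 1.34 * (c2v / np.linalg.norm(c2v))
    names += ["O6", "N2"]
    elems += ["O", "N"]
    coords += [o6, n2]
    coords = np.vstack(coords) + np.asarray(center)
    return names, elems, coords


def _sphere_sphere_point(c1: np.ndarray, r1: float, c2: np.ndarray,
                         r2: float, prefer_dir: np.ndarray) -> np.ndarray:
    """A point on the intersection circle of two spheres, chosen
    deterministically toward ``prefer_dir``."""
    axis = c2 - c1
    dist = np.linalg.norm(axis)
    if dist > r1 + r2 or dist < abs(r1 - r2) or dist < 1e-9:
        raise FixtureSpecError("H-bond geometry unreachable in ladder")
    axis = axis / dist
    x = (dist**2 + r1**2 - r2**2) / (2 * dist)
    rho = np.sqrt(max(r1**2 - x**2, 0.0))
    center = c1 + x * axis
    p = prefer_dir - np.dot(prefer_dir, axis) * axis
    if np.linalg.norm(p) < 1e-9:
        p = np.cross(axis, [0.0, 0.0, 1.0])
        if np.linalg.norm(p) < 1e-9:
            p = np.cross(axis, [1.0, 0.0, 0.0])
    p = p / np.linalg.norm(p)
    return center + rho * p


RISE = 3.4           # A, stack rise
TWIST = 36.0         # degrees per step
BASE_RADIUS = 4.0    # A, displacement of base centers from the helix axis
_ARG_AZ_OFFSET = -50.0   # deg, Arg azimuth relative to its base (backward)
_ARG_LATERAL = 1.2       # A, NH1 radial offset beyond the base center
_ARG_HEIGHT = 3.2        # A, NH1 height above the base plane


def generate_stair_fixture(n_steps: int, seed: int = 0
                           ) -> tuple[str, str, dict]:
    """A stacked guanine ladder with ``n_steps`` Arg residues, each making a
    cation-pi interaction with base s and an H-bond (NH2 to O6) with base
    s+1, plus the matching .hb2 text.  Truth: exactly ``n_steps`` motifs.

    Base centers sit on a circle of radius 4 A around the helix axis (rise
    3.4 A, twist 36 deg per step); each guanine is oriented with its O6
    pointing toward the preceding step's Arg so the H-bond geometry closes,
    and each Arg guanidinium hovers over the outer edge of its own base,
    clear of the neighbouring bases.
    """
    if n_steps < 0:
        raise FixtureSpecError("n_steps must be >= 0")
    n_bases = max(n_steps + 1, 2)
    base_sets = []
    hex_centers = []
    for s in range(n_bases):
        az = TWIST * s
        center = np.array([
            BASE_RADIUS * np.cos(np.radians(az)),
            BASE_RADIUS * np.sin(np.radians(az)),
            RISE * s,
        ])
        # orient C6 (vertex 5, which bears O6) toward the previous step's Arg
        phase = (TWIST * (s - 1) + _ARG_AZ_OFFSET) - 300.0
        names, elems, coords = _ideal_guanine(np.zeros(3), phase)
        coords = coords + center
        base_sets.append((names, elems, coords))
        hex_centers.append(center)

    hbond_specs = []
    arg_sets = []
    for s in range(n_steps):
        az_arg = np.radians(TWIST * s + _ARG_AZ_OFFSET)
        cen_i = hex_centers[s]
        nh1 = np.array([
            (BASE_RADIUS + _ARG_LATERAL) * np.cos(az_arg),
            (BASE_RADIUS + _ARG_LATERAL) * np.sin(az_arg),
            cen_i[2] + _ARG_HEIGHT,
        ])
        names_j, _, coords_j = base_sets[s + 1]
        o6_j = coords_j[names_j.index("O6")]
        prefer = nh1 - np.array([0.0, 0.0, nh1[2]])   # radially outward
        nh2 = _sphere_sphere_point(nh1, 2.30, o6_j, 2.85, prefer)
        nn_u = (nh2 - nh1) / np.linalg.norm(nh2 - nh1)
        mid = 0.5 * (nh1 + nh2)
        m = np.cross([0.0, 0.0, 1.0], nn_u)
        if np.linalg.norm(m) < 1e-9:
            m = np.cross([1.0, 0.0, 0.0], nn_u)
        m = m / np.linalg.norm(m)
        if np.dot(m, mid - np.array([0.0, 0.0, mid[2]])) < 0:
            m = -m                                    # CZ/NE point outward
        cz = mid + 0.665 * m
        ne = cz + 1.33 * m
        arg_sets.append((["NH1", "NH2", "CZ", "NE"], ["N", "N", "C", "N"],
                         np.vstack([nh1, nh2, cz, ne])))
        hbond_specs.append((s, ("A", 100 + s, ""), "NH2",
                            ("B", 1 + s + 1, ""), "O6"))

    lines = []
    serial = 1
    for s, (names, elems, coords) in enumerate(arg_sets):
        for name, elem, xyz in zip(names, elems, coords):
            lines.append(_pdb_atom_line(serial, name, elem, "ARG", "A",
                                        100 + s, xyz))
            serial += 1
    if arg_sets:
        lines.append("TER")
    for s, (names, elems, coords) in enumerate(base_sets):
        for name, elem, xyz in zip(names, elems, coords):
            lines.append(_pdb_atom_line(serial, name, elem, "DG", "B",
                                        1 + s, xyz))
            serial += 1
    lines.append("TER")
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    hb2_lines = ["synthetic ladder hydrogen bonds (HBPLUS-compatible layout)"]
    for s, donor_id, datom, acc_id, aatom in hbond_specs:
        nh2 = arg_sets[s][2][1]
        names_j, _, coords_j = base_sets[s + 1]
        da = float(np.linalg.norm(nh2 - coords_j[names_j.index("O6")]))
        hb2_lines.append(
            f"{donor_id[0]}{donor_id[1]:04d}-ARG {datom:<4s}"
            f"{acc_id[0]}{acc_id[1]:04d}- DG {aatom:<4s}{da:5.2f}")
    hb2_text = "\n".join(hb2_lines) + "\n"

    truth = {
        "n_motifs": n_steps,
        "n_bases": n_bases,
        "amino_acids": [("A", 100 + s, "") for s in range(n_steps)],
        "base_pairs": [(("B", 1 + s, ""), ("B", 2 + s, ""))
                       for s in range(n_steps)],
    }
    return pdb_text, hb2_text, truth
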