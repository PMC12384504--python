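# Methods

Full definitions of the geometric criteria and decision rules implemented by
`pistacks`. All distances are in Å, all angles in degrees.

## 1. Structure model

PDB files are parsed with gemmi. Only the first MODEL is used. For
alternate locations the highest-occupancy conformer is kept, ties resolved
toward altloc `A` (policy `FIRST` keeps the first encountered instead).
Waters are excluded. Every residue is classified as amino acid, nucleotide,
ligand (HETATM entity with a registered ring system) or other; selenomethionine
(MSE) maps to MET by default.

An analysis **scope** limits which residue pairs are considered:

- `intra` (default): all pairs within the structure, optionally restricted
  to a chain subset;
- `interface(group1, group2)`: only pairs with one residue in each chain
  group; the groups must be disjoint, non-empty, and present in the file.

## 2. Functional groups

| group | residues | atoms |
|---|---|---|
| aromatic ring | Phe, Tyr | CG CD1 CD2 CE1 CE2 CZ |
| aromatic ring | His | CG ND1 CD2 CE1 NE2 |
| fused system | Trp | 6-ring CD2 CE3 CZ3 CH2 CZ2 CE2 + 5-ring CG CD1 NE1 |
| aromatic ring | nucleobases | standard base atoms (purines: fused 6+5) |
| ligand rings | e.g. ATP adenine | JSON registry `data/groups.json` |
| cation | Arg | NH1 NH2 CZ NE (planar) |
| cation | Lys | NZ CE (+ HZ atoms when present) |
| amide | Asn / Gln | OD1 ND2 CG / OE1 NE2 CD (planar) |
| His triad | His | ND1 CE1 NE2 (when His is the non-ring partner) |
| sulfur | Met / Cys | SD (+CG, CE) / SG (+CB) |

Groups with missing atoms are skipped with a warning. Ring planes are
least-squares fits (smallest-eigenvalue eigenvector of the centred covariance
matrix); the ring radius `r` is the mean centroid-to-atom distance.

## 3. Pair criteria

For an ordered pair (ring group 1, partner group 2):

1. `d`, `atom1`, `atom2` — the minimum heavy-atom distance between the two
   groups and the atoms realising it (lexicographic tie-break on atom names).
2. For fused systems, the ring used for the cylinder test is the one whose
   centroid is closest to the system's own contact atom; an exact tie goes to
   the 6-membered ring.
3. `α` — angle at the ring centroid between the ring normal and the vector
   to the partner's contact atom, folded into [0, 90] by orienting the normal
   toward the atom. The atom passes the cylinder test when its lateral
   offset `|CA|·sin α` is ≤ `rmax`, with `rmax = 2r` (3r for π-π).
4. Distance caps: π-π ≤ 5.0, sulfur-π ≤ 6.0, cation-/amino-/His-π ≤ 4.5.
5. `β` — reported when both groups are planar (π-π, amino-π, His-π, and
   cation-π with Arg): the smallest angle between the two plane normals,
   folded into [0, 90].

π-π is evaluated symmetrically: the cylinder test is run from both rings and
the orientation with the smaller α is reported, so detection is invariant to
argument order.

### Typing precedence

- His ring vs. any aromatic ring → `his_pi` (never `pi_pi`); the aromatic
  ring is partner 1 and the His triad partner 2. His vs. His yields a single
  record (minimum-α orientation).
- Arg/Lys cation vs. His ring → `cation_pi` with the His ring as partner 1.
- All thresholds are user-overridable (`Thresholds`, or a YAML file via
  `--thresholds`); unknown keys are rejected.

## 4. Context labels

`intra` (same chain / within scope), `interface` (across scope chain
groups), `protein_ligand`, `protein_NA` (amino acid vs. nucleotide),
`base_base` (nucleotide vs. nucleotide). `base_base` records feed stair
detection but are excluded from π-chains and frequency counts.

## 5. π-chains

Build a graph whose nodes are residues and whose edges are detected
interaction records (excluding `base_base`). Every connected component with
≥ 2 edges is a π-chain, reported with its members (sorted), edges and a
per-type tally. Components are ordered by their lowest member id.

## 6. Stair motifs

A stair motif is a triple (amino acid `A`, base `B_i`, base `B_j`) such that

1. `A` makes a cation-π, amino-π or His-π interaction to `B_i`;
2. `B_i` and `B_j` are consecutive in sequence (same chain, |Δseq| = 1) and
   their bases stack (a `base_base` π-π record);
3. `A` donates or accepts a hydrogen bond to a **base** atom of `B_j`
   (sugar/phosphate atoms are excluded unless `base_atoms_only=False`).

Hydrogen bonds come from HBPLUS-style `.hb2` files (fixed-width parser with
round-tripping writer) or from a built-in geometric fallback (donor–acceptor
distance ≤ 3.5 with a D–H···A angle check when hydrogens are present).

## 7. Frequencies and distributions

A **contact** is an unordered residue pair whose side-chain heavy atoms come
within 5.0 (for nucleotides the whole base counts as side chain; Gly has
none). The relative frequency of an interaction type in a structure is
`100 · count / contacts`; batch statistics are the per-structure mean and
population standard deviation. Geometry distributions are histograms of `d`,
`1 − cos α` or `1 − cos β` (records without β are excluded from β
histograms), with normalised densities and a mode helper.

## 8. Synthetic fixtures

`generate_pair_fixture(FixtureSpec(...))` constructs a two-residue PDB with a
requested interaction type and exact target geometry (d, α or lateral
offset, β where defined), optional seeded jitter, and returns a truth record
(expected detection outcome, achieved geometry, thresholds used). The truth
record is computed from the coordinates as written to the file (3 decimals),
so truth and detector agree even exactly at threshold boundaries; poses whose
designated contact atom cannot remain the closest atom raise
`FixtureSpecError`. `generate_stair_fixture(n)` builds a B-DNA-like guanine
ladder (rise 3.4, twist 36°) with one arginine per step plus a matching
`.hb2` file, yielding exactly `n` stair motifs. `pistacks.scenes` provides
three labelled demonstration scenes (protein–ligand, nine-member π-chain,
two-chain interface) with hand-verified geometry.
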