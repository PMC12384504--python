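# pistacks

Geometric detection of π-mediated interactions — π-π, cation-π, amino-π,
His-π and sulfur-π — in protein and protein–nucleic-acid structures, plus
assembly of higher-order **π-chains** (connected networks of successive π
interactions) and **stair motifs** (two stacked nucleobases bridged by an
amino acid that makes a π interaction to one base and a hydrogen bond to the
next).

## How it works

For every candidate residue pair the detector:

1. extracts the functional groups involved — aromatic rings (Phe, Tyr, Trp,
   His, nucleobases, aromatic ligand rings defined in a JSON registry),
   cationic groups (Arg guanidinium, Lys ammonium), planar amides (Asn, Gln),
   the His ND1/CE1/NE2 triad, and sulfur atoms (Met SD, Cys SG);
2. finds the **closest heavy-atom pair** between the two groups; its distance
   is `d`;
3. fits a least-squares plane to each ring and erects an acceptance cylinder
   of radius `rmax = 2r` (`3r` for π-π) on it, where `r` is the mean
   centroid-to-atom ring radius; the partner's closest atom must fall inside
   the cylinder, i.e. its lateral offset `|CA|·sin α ≤ rmax`, with `α` the
   angle between the centroid→atom vector and the ring normal;
4. applies the per-type distance cap: 5.0 Å (π-π), 6.0 Å (sulfur-π), 4.5 Å
   (cation-π, amino-π, His-π);
5. types the interaction with His precedence (a His ring facing any aromatic
   ring is His-π, not π-π; a cation facing a His ring is cation-π) and, when
   both groups are planar, reports `β`, the angle between the two plane
   normals folded into [0°, 90°] (0° = stacked, 90° = T-shaped).

Records carry a context label (`intra`, `interface`, `protein_ligand`,
`protein_NA`, `base_base`). π-chains are connected components (≥2 edges) of
the record graph; stair motifs combine a base–base stack, an amino-acid π
interaction to one base and a hydrogen bond (HBPLUS `.hb2` file or a built-in
geometric fallback) to the adjacent stacked base. Frequencies are normalised
per 100 side-chain contacts (residue pairs with side-chain heavy atoms within
5 Å).

## Worked example

The package ships deterministic demonstration scenes
(`pistacks.scenes`). The π-chain scene is a stack of four phenylalanines, a
lysine ammonium, another ring, and two methionine sulfurs — nine residues
linked by eight successive π interactions:

```python
from pathlib import Path
from pistacks import scenes

Path("demo").mkdir(exist_ok=True)
Path("demo/tower.pdb").write_text(scenes.pi_chain_scene())
```

```sh
$ pistacks demo --report-frequencies
1 structure(s), 8 interaction record(s)
```

`demo/PInteract.csv` then contains one row per interaction:

```text
structure,itype,chain1,resnum1,icode1,resname1,group1,ring_used,chain2,resnum2,icode2,resname2,group2,atom1,atom2,d,alpha,beta,context
tower,pi_pi,A,2,,PHE,aromatic_ring,6,A,1,,PHE,aromatic_ring,CD1,CD1,3.800,20.09,0.00,intra
tower,pi_pi,A,2,,PHE,aromatic_ring,6,A,3,,PHE,aromatic_ring,CD1,CD1,3.800,20.09,0.00,intra
tower,pi_pi,A,3,,PHE,aromatic_ring,6,A,4,,PHE,aromatic_ring,CD1,CD1,3.800,20.09,0.00,intra
tower,cation_pi,A,4,,PHE,aromatic_ring,6,A,5,,LYS,cation,CG,CE,3.502,23.20,,intra
tower,cation_pi,A,6,,PHE,aromatic_ring,6,A,5,,LYS,cation,CG,CE,3.502,23.20,,intra
tower,sulfur_pi,A,6,,PHE,aromatic_ring,6,A,7,,MET,sulfur,CG,SD,4.235,0.00,,intra
tower,sulfur_pi,A,8,,PHE,aromatic_ring,6,A,7,,MET,sulfur,CG,SD,4.235,0.00,,intra
tower,sulfur_pi,A,8,,PHE,aromatic_ring,6,A,9,,MET,sulfur,CG,SD,4.235,0.00,,intra
```

and `demo/PInteract1.csv` reports the assembled π-chain (all nine residues in
one component, tally 3 π-π / 2 cation-π / 3 sulfur-π):

```text
structure,entry,n_members,n_edges,members,type_counts
tower,chain1,9,8,A/1/;A/2/;A/3/;A/4/;A/5/;A/6/;A/7/;A/8/;A/9/,cation_pi=2;pi_pi=3;sulfur_pi=3
```

The same analysis is available as a library:

```python
from pistacks import parse_pdb, detect_all, find_pi_chains

s = parse_pdb("demo/tower.pdb")
records = detect_all(s)          # 8 InteractionRecord objects
chains = find_pi_chains(records)  # 1 chain, 9 members
```

Interface analyses restrict detection to residue pairs across two chain
groups (`pistacks demo --scope interface --chains H:Y`); directories
containing `.hb2` files next to their PDB files get stair-motif detection
automatically.

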