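"""interaction_detector: typing rules, thresholds and detection invariants."""

import numpy as np
import pytest

from pistacks import (Context, FixtureSpec, InteractionType, Scope,
                      Thresholds, detect_all, detect_pair,
                      generate_pair_fixture)
from pistacks.fixtures import SIDE6, regular_polygon
from pistacks.model import Structure

from conftest import load_structure, make_residue, make_structure

RING6 = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]


def _ring_residue(resname, center, chain="A", seq=1):
    coords = regular_polygon(6, SIDE6) + np.asarray(center, float)
    return make_residue(resname, {n: ("C", coords[i])
                                  for i, n in enumerate(RING6)},
                        chain=chain, seq=seq)


def _his_residue(center, chain="A", seq=1):
    pent = regular_polygon(5, 1.37) + np.asarray(center, float)
    names = ["CG", "ND1", "CD2", "CE1", "NE2"]
    return make_residue("HIS", {n: ("N" if n.startswith("N") else "C", pent[i])
                                for i, n in enumerate(names)},
                        chain=chain, seq=seq)


def test_thresholds_validation_and_file_roundtrip(tmp_path):
    with pytest.raises(ValueError):
        Thresholds(dmax_pipi=-1.0)
    p = tmp_path / "th.yaml"
    p.write_text("dmax_pipi: 6.5\nrmax_multiplier_other: 2.5\n")
    th = Thresholds.from_file(p)
    assert th.dmax_pipi == 6.5
    assert th.rmax_multiplier_other == 2.5
    assert th.dmax_sulfur == 6.0          # untouched default
    p.write_text("no_such_key: 1\n")
    with pytest.raises(ValueError):
        Thresholds.from_file(p)


def test_detect_pair_fixture_cation_pi_on_axis(tmp_path):
    spec = FixtureSpec("cation_pi", target_d=3.5, target_alpha=0.0,
                       variant="LYS")
    text, truth = generate_pair_fixture(spec)
    s = load_structure(tmp_path, text)
    recs = detect_all(s)
    assert [r.itype for r in recs] == [InteractionType.CATION_PI]
    g = recs[0].geometry
    assert abs(g.d - 3.5) < 1e-3
    assert g.alpha < 0.1
    assert recs[0].partner1.group_kind == "aromatic_ring"
    assert recs[0].partner2.resname == "LYS"
    assert g.beta is None                 # Lys ammonium is not planar


def test_detect_pair_symmetry_in_argument_order():
    r1 = _ring_residue("PHE", (0, 0, 0), seq=1)
    r2 = _ring_residue("TYR", (0, 0, 3.8), seq=2)
    a = detect_pair(r1, r2)
    b = detect_pair(r2, r1)
    assert len(a) == len(b) == 1
    assert a[0].sort_key() == b[0].sort_key()
    assert abs(a[0].geometry.d - b[0].geometry.d) < 1e-12
    assert abs(a[0].geometry.alpha - b[0].geometry.alpha) < 1e-12


def test_detect_pair_same_residue_returns_empty():
    r = _ring_residue("PHE", (0, 0, 0))
    assert detect_pair(r, r) == []


def test_two_ala_residues_no_interaction():
    a1 = make_residue("ALA", {"CB": ("C", (0, 0, 0))}, seq=1)
    a2 = make_residue("ALA", {"CB": ("C", (0, 0, 3))}, seq=2)
    assert detect_pair(a1, a2) == []


def test_his_precedence_over_pi_pi():
    his = _his_residue((0, 0, 0), seq=1)
    phe = _ring_residue("PHE", (0, 0, 3.6), seq=2)
    recs = detect_pair(his, phe)
    assert [r.itype for r in recs] == [InteractionType.HIS_PI]
    # the non-His ring is partner 1, the His triad partner 2
    assert recs[0].partner1.resname == "PHE"
    assert recs[0].partner2.resname == "HIS"
    assert recs[0].partner2.group_kind == "cation"


def test_his_his_keeps_single_record_with_smaller_alpha():
    h1 = _his_residue((0, 0, 0), seq=1)
    h2 = _his_residue((0.8, 0, 3.6), seq=2)
    recs = detect_pair(h1, h2)
    assert len(recs) == 1
    assert recs[0].itype is InteractionType.HIS_PI


def test_arg_lys_vs_his_ring_is_cation_pi():
    his = _his_residue((0, 0, 0), seq=1)
    lys = make_residue("LYS", {"NZ": ("N", (0, 0, 3.5)),
                               "CE": ("C", (1.5, 0, 3.5))}, seq=2)
    recs = detect_pair(his, lys)
    assert [r.itype for r in recs] == [InteractionType.CATION_PI]
    assert recs[0].partner1.resname == "HIS"     # His ring is the aromatic


def test_threshold_monotonicity_on_fixture(tmp_path):
    spec = FixtureSpec("cation_pi", target_d=4.4, target_alpha=10.0,
                       variant="LYS")
    text, truth = generate_pair_fixture(spec)
    assert truth.expected_detected
    s = load_structure(tmp_path, text)
    assert len(detect_all(s)) == 1
    # shrinking dmax below d removes the record
    tight = Thresholds(dmax_cat_amino_his=4.0)
    assert detect_all(s, tight) == []
    # enlarging thresholds never removes records
    loose = Thresholds(dmax_pipi=7.0, dmax_sulfur=7.0, dmax_cat_amino_his=6.0,
                       rmax_multiplier_pipi=4.0, rmax_multiplier_other=3.0)
    assert len(detect_all(s, loose)) >= 1


def test_all_five_types_via_fixtures(tmp_path):
    specs = [
        FixtureSpec("pi_pi", 3.8, target_alpha=20.0, target_beta=30.0),
        FixtureSpec("cation_pi", 4.0, target_alpha=10.0, variant="LYS"),
        FixtureSpec("cation_pi", 4.0, target_alpha=10.0, target_beta=45.0,
                    variant="ARG"),
        FixtureSpec("amino_pi", 4.0, target_alpha=15.0, target_beta=60.0),
        FixtureSpec("his_pi", 4.0, target_alpha=15.0, target_beta=0.0),
        FixtureSpec("sulfur_pi", 5.0, target_alpha=30.0),
    ]
    for k, spec in enumerate(specs):
        text, truth = generate_pair_fixture(spec)
        s = load_structure(tmp_path, text, f"f{k}")
        recs = [r for r in detect_all(s) if r.itype.value == spec.pair_type]
        assert len(recs) == 1, spec.pair_type
        g = recs[0].geometry
        assert abs(g.d - truth.d) < 1e-6
        assert abs(g.alpha - truth.alpha) < 1e-6
        if truth.beta is None:
            assert g.beta is None
        else:
            assert abs(g.beta - truth.beta) < 1e-6
        # every record satisfies its own invariants
        assert g.d <= Thresholds().dmax(recs[0].itype)
        assert 0.0 <= g.alpha <= 90.0
        assert g.beta is None or 0.0 <= g.beta <= 90.0


def test_detect_all_permutation_invariance(tower_structure):
    base = [(r.sort_key(), round(r.geometry.d, 9))
            for r in detect_all(tower_structure)]
    shuffled = Structure(id="shuffled")
    residues = list(tower_structure.residues())[::-1]
    for r in residues:
        shuffled.chains.setdefault(r.chain_id, []).append(r)
    permuted = [(r.sort_key(), round(r.geometry.d, 9))
                for r in detect_all(shuffled)]
    assert base == permuted


def test_context_assignment(ligand_structure, interface_structure,
                            tower_structure):
    assert {r.context for r in detect_all(ligand_structure)} == \
        {Context.PROTEIN_LIGAND}
    assert {r.context for r in detect_all(interface_structure)} == \
        {Context.INTERFACE}
    assert {r.context for r in detect_all(tower_structure)} == {Context.INTRA}


def test_interface_scope_limits_pairs(interface_structure, tmp_path):
    recs = detect_all(interface_structure)
    keys = {(r.itype.value, r.partner1.residue_id, r.partner2.residue_id)
            for r in recs}
    assert keys == {
        ("cation_pi", ("H", 30, ""), ("Y", 97, "")),
        ("pi_pi", ("H", 53, ""), ("Y", 62, "")),
    }
    # same structure, intra scope: the same two records (the H-H and Y-Y
    # residue pairs are too far apart to add anything)
    interface_structure.scope = Scope.intra()
    assert len(detect_all(interface_structure)) == 2


def test_base_base_records_emitted_regardless_of_scope(tmp_path):
    from pistacks import generate_stair_fixture
    pdb, hb2, truth = generate_stair_fixture(2, seed=0)
    s = load_structure(tmp_path, pdb, "ladder")
    s.scope = Scope.interface({"A"}, {"B"})
    recs = detect_all(s)
    stacks = [r for r in recs if r.context is Context.BASE_BASE]
    assert len(stacks) == 2               # three bases -> two stacked pairs
    assert all(r.itype is InteractionType.PI_PI for r in stacks)
    cats = [r for r in recs if r.itype is InteractionType.CATION_PI]
    assert len(cats) == 2
    assert all(r.context is Context.PROTEIN_NA for r in cats)
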