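"""structure_model: parsing, classification, scope and pair enumeration."""

import numpy as np
import pytest

from pistacks import (AltlocPolicy, FixtureSpec, Scope, ScopeError,
                      StructureError, classify_residue, detect_all,
                      generate_pair_fixture, iter_candidate_pairs, parse_pdb)
from pistacks.fixtures import _pdb_atom_line
from pistacks.model import EntityKind

from conftest import load_structure


def _atom_line(serial, name, elem, resname, chain, seq, xyz, altloc=" ",
               occ=1.00):
    pad = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (f"ATOM  {serial:5d} {pad}{altloc}{resname:>3s} {chain}"
            f"{seq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {elem:>2s}")


def test_parse_minimal_single_residue(tmp_path):
    text = "\n".join([
        _atom_line(1, "N", "N", "ALA", "A", 1, (0.0, 0.0, 0.0)),
        _atom_line(2, "CA", "C", "ALA", "A", 1, (1.5, 0.0, 0.0)),
        _atom_line(3, "CB", "C", "ALA", "A", 1, (2.0, 1.4, 0.0)),
        "END",
    ]) + "\n"
    s = load_structure(tmp_path, text)
    assert list(s.chains) == ["A"]
    assert s.n_residues() == 1
    res = next(s.residues())
    assert len(res.atoms) == 3
    assert res.entity_kind is EntityKind.AMINO_ACID
    # coordinates survive parsing to PDB precision
    assert np.allclose(res.atom("CB").coord, [2.0, 1.4, 0.0], atol=1e-3)


def test_altloc_highest_occupancy_kept(tmp_path):
    text = "\n".join([
        _atom_line(1, "CB", "C", "ALA", "A", 1, (0.0, 0.0, 0.0), "A", 0.60),
        _atom_line(2, "CB", "C", "ALA", "A", 1, (9.0, 9.0, 9.0), "B", 0.40),
        "END",
    ]) + "\n"
    s = load_structure(tmp_path, text)
    res = next(s.residues())
    assert len(res.atoms) == 1
    assert np.allclose(res.atom("CB").coord, [0.0, 0.0, 0.0], atol=1e-3)


def test_altloc_tie_prefers_a_and_first_policy(tmp_path):
    text = "\n".join([
        _atom_line(1, "CB", "C", "ALA", "A", 1, (9.0, 9.0, 9.0), "B", 0.50),
        _atom_line(2, "CB", "C", "ALA", "A", 1, (0.0, 0.0, 0.0), "A", 0.50),
        "END",
    ]) + "\n"
    p = tmp_path / "t.pdb"
    p.write_text(text)
    res = next(parse_pdb(p).residues())
    assert np.allclose(res.atom("CB").coord, [0.0, 0.0, 0.0], atol=1e-3)
    res = next(parse_pdb(p, altloc_policy=AltlocPolicy.FIRST).residues())
    assert np.allclose(res.atom("CB").coord, [9.0, 9.0, 9.0], atol=1e-3)


def test_waters_excluded(tmp_path):
    text = "\n".join([
        _atom_line(1, "CB", "C", "ALA", "A", 1, (0.0, 0.0, 0.0)),
        _atom_line(2, "O", "O", "HOH", "A", 2, (5.0, 0.0, 0.0)),
        "END",
    ]) + "\n"
    s = load_structure(tmp_path, text)
    assert s.n_residues() == 1


def test_unreadable_and_empty_inputs_raise(tmp_path):
    with pytest.raises(StructureError):
        parse_pdb(tmp_path / "missing.pdb")
    p = tmp_path / "empty.pdb"
    p.write_text("REMARK nothing here\nEND\n")
    with pytest.raises(StructureError):
        parse_pdb(p)


def test_classify_residue_table():
    aa_atoms = {"N", "CA", "C", "O", "CB"}
    assert classify_residue("TRP", aa_atoms) is EntityKind.AMINO_ACID
    assert classify_residue("HOH", {"O"}) is EntityKind.OTHER
    assert classify_residue("DA", {"N1"}) is EntityKind.DEOXYRIBONUCLEOTIDE
    assert classify_residue("U", {"N1"}) is EntityKind.RIBONUCLEOTIDE
    adenine = {"N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"}
    assert classify_residue("ATP", adenine) is EntityKind.LIGAND
    # without the full ring template the ligand is not recognised
    assert classify_residue("ATP", adenine - {"N9"}) is EntityKind.OTHER
    assert classify_residue("XYZ", {"C1"}) is EntityKind.OTHER
    with pytest.raises(ValueError):
        classify_residue("", set())


def test_classify_mse_mapping():
    atoms = {"N", "CA", "C", "O", "CB", "CG", "SE"}
    assert classify_residue("MSE", atoms) is EntityKind.AMINO_ACID
    assert classify_residue("MSE", atoms, map_mse=False) is EntityKind.OTHER


def test_fixture_roundtrip_preserves_geometry(tmp_path):
    spec = FixtureSpec("pi_pi", target_d=3.8, target_alpha=20.0,
                       target_beta=30.0)
    text, truth = generate_pair_fixture(spec)
    s = load_structure(tmp_path, text)
    recs = detect_all(s)
    assert len(recs) == 1
    g = recs[0].geometry
    # the parsed file carries exactly the generated (rounded) coordinates,
    # so the detector must agree with the truth record almost exactly
    assert abs(g.d - truth.d) < 1e-6
    assert abs(g.alpha - truth.alpha) < 1e-6
    # and both sit within PDB precision of the request
    assert abs(g.d - 3.8) < 2e-3
    assert abs(g.alpha - 20.0) < 0.1


def test_iter_pairs_basic_counts(tmp_path):
    lines = [
        _atom_line(1, "CB", "C", "ALA", "A", 1, (0.0, 0.0, 0.0)),
        _atom_line(2, "CB", "C", "ALA", "A", 2, (3.0, 0.0, 0.0)),
        "END",
    ]
    s = load_structure(tmp_path, "\n".join(lines) + "\n")
    assert len(list(iter_candidate_pairs(s))) == 1

    lines = []
    serial = 1
    for seq in (1, 2, 3):
        lines.append(_atom_line(serial, "CB", "C", "ALA", "A", seq,
                                (seq * 2.0, 0.0, 0.0)))
        serial += 1
    for seq in (1, 2):
        lines.append(_atom_line(serial, "CB", "C", "ALA", "B", seq,
                                (seq * 2.0, 3.0, 0.0)))
        serial += 1
    s = load_structure(tmp_path, "\n".join(lines + ["END"]) + "\n", "two")
    s.scope = Scope.interface({"A"}, {"B"})
    assert len(list(iter_candidate_pairs(s))) == 6


def test_iter_pairs_matches_bruteforce(tmp_path):
    rng = np.random.default_rng(7)
    lines = []
    for i in range(20):
        xyz = rng.uniform(0, 15, 3)
        lines.append(_atom_line(i + 1, "CB", "C", "ALA", "A", i + 1, xyz))
    s = load_structure(tmp_path, "\n".join(lines + ["END"]) + "\n", "rand")
    brute = {frozenset((a.id, b.id))
             for a, b in iter_candidate_pairs(s, prefilter=False)}
    residues = list(s.residues())
    expected = {frozenset((residues[i].id, residues[j].id))
                for i in range(len(residues))
                for j in range(i + 1, len(residues))}
    assert brute == expected
    filtered = {frozenset((a.id, b.id)) for a, b in iter_candidate_pairs(s)}
    assert filtered <= brute


def test_detect_all_identical_with_prefilter_on_off(tower_structure):
    def key(rec):
        return (rec.sort_key(), round(rec.geometry.d, 6),
                round(rec.geometry.alpha, 6))
    on = [key(r) for r in detect_all(tower_structure, prefilter=True)]
    off = [key(r) for r in detect_all(tower_structure, prefilter=False)]
    assert on == off and len(on) == 8


def test_min_seq_separation_filters_same_chain_pairs(tower_structure):
    recs = detect_all(tower_structure, min_seq_separation=3)
    # only edges spanning >= 3 in sequence survive (none in the tower,
    # where every interacting pair is 1 or 2 apart)
    assert all(abs(r.partner1.residue_id[1] - r.partner2.residue_id[1]) >= 3
               for r in recs)
    assert len(recs) < 8


def test_scope_validation_errors(tmp_path):
    with pytest.raises(ValueError):
        Scope.interface({"A"})
    with pytest.raises(ValueError):
        Scope.interface({"A", "B"}, {"B"})
    text = _atom_line(1, "CB", "C", "ALA", "A", 1, (0.0, 0.0, 0.0))
    s = load_structure(tmp_path, text + "\nEND\n")
    s.scope = Scope.interface({"A"}, {"Z"})
    with pytest.raises(ScopeError):
        list(iter_candidate_pairs(s))
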