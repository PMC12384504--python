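"""Shared helpers for the test suite: structure loading and residue builders."""

from __future__ import annotations

import numpy as np
import pytest

from pistacks import Scope, parse_pdb
from pistacks.model import Atom, EntityKind, Residue, Structure, classify_residue
from pistacks import scenes


def load_structure(tmp_path, text, name="s"):
    p = tmp_path / f"{name}.pdb"
    p.write_text(text)
    return parse_pdb(p)


def make_residue(resname, atoms, chain="A", seq=1, icode=""):
    """Build a Residue directly from {atom_name: (element, xyz)}."""
    alist = [Atom(name=n, element=e, coord=np.asarray(xyz, float))
             for n, (e, xyz) in atoms.items()]
    res = Residue(chain_id=chain, seqnum=seq, icode=icode,
                  resname=resname, atoms=alist)
    res.entity_kind = classify_residue(resname, res.atom_names())
    return res


def make_structure(residues, sid="test"):
    s = Structure(id=sid)
    for r in residues:
        s.chains.setdefault(r.chain_id, []).append(r)
    return s


@pytest.fixture
def ligand_structure(tmp_path):
    return load_structure(tmp_path, scenes.ligand_scene(), "ligand")


@pytest.fixture
def tower_structure(tmp_path):
    return load_structure(tmp_path, scenes.pi_chain_scene(), "tower")


@pytest.fixture
def interface_structure(tmp_path):
    s = load_structure(tmp_path, scenes.interface_scene(), "iface")
    s.scope = Scope.interface({"H"}, {"Y"})
    return s
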