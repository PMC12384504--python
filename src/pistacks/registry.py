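"""Functional-group registry.

The atom compositions of the interacting groups (aromatic rings, cationic
and amide groups, sulfur atoms, nucleobase rings and nucleobase-carrying
ligand templates) are shipped as a JSON data file so that users can register
additional ligand codes without touching code.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from pathlib import Path

_EXTRA_LIGANDS: dict[str, list[dict]] = {}


@lru_cache(maxsize=1)
def _builtin() -> dict:
    with resources.files("pistacks.data").joinpath("groups.json").open() as fh:
        return json.load(fh)


def amino_acid_groups() -> dict:
    return _builtin()["amino_acids"]


def nucleobase_groups() -> dict:
    return _builtin()["nucleobases"]


def base_atom_names(resname: str) -> frozenset[str] | None:
    """All heavy atoms of the nucleobase moiety (ring plus substituents)."""
    entry = _builtin()["nucleobases"].get(resname.upper())
    if entry is None:
        return None
    return frozenset(entry["base_atoms"])


def ligand_templates() -> dict[str, list[dict]]:
    merged = dict(_builtin()["ligands"])
    merged.update(_EXTRA_LIGANDS)
    return merged


def register_ligand(code: str, systems: list[dict]) -> None:
    """Register a nucleobase-carrying ligand at run time.

    ``systems`` follows the JSON layout: a list of aromatic systems, each a
    dict with a ``rings`` list of ``{"size": 5|6, "atoms": [...]}``.
    """
    _EXTRA_LIGANDS[code.upper()] = systems


def load_ligand_file(path: str | Path) -> None:
    """Merge user-supplied ligand templates from a JSON file."""
    data = json.loads(Path(path).read_text())
    for code, systems in data.items():
        register_ligand(code, systems)


def ligand_ring_codes() -> frozenset[str]:
    return frozenset(ligand_templates())


def ligand_template_matches(resname: str, atom_names: frozenset[str]) -> bool:
    """True when a registered ligand template's ring atoms are all present."""
    systems = ligand_templates().get(resname.upper())
    if not systems:
        return False
    for system in systems:
        for ring in system["rings"]:
            if not set(ring["atoms"]) <= atom_names:
                break
        else:
            return True
    return False
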