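{
  "_comment": "Functional-group atom registry. Rings are ordered 6-ring first for fused systems; 'bridge' names the two atoms shared by fused rings. Users may extend 'ligands' with additional nucleobase-carrying HETATM codes via pistacks.registry.load_ligand_file.",
  "amino_acids": {
    "PHE": {
      "rings": [{"rings": [{"size": 6, "atoms": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]}]}]
    },
    "TYR": {
      "rings": [{"rings": [{"size": 6, "atoms": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]}]}]
    },
    "TRP": {
      "rings": [{"rings": [{"size": 6, "atoms": ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]},
                            {"size": 5, "atoms": ["CG", "CD1", "NE1", "CE2", "CD2"]}],
                 "bridge": ["CD2", "CE2"]}]
    },
    "HIS": {
      "rings": [{"rings": [{"size": 5, "atoms": ["CG", "ND1", "CD2", "CE1", "NE2"]}]}],
      "cation": {"atoms": ["ND1", "CE1", "NE2"], "planar": true}
    },
    "ARG": {
      "cation": {"atoms": ["NH1", "NH2", "CZ", "NE"], "planar": true}
    },
    "LYS": {
      "cation": {"atoms": ["NZ", "CE"], "planar": false,
                 "optional_hydrogens": ["HZ1", "HZ2", "HZ3", "1HZ", "2HZ", "3HZ", "H1", "H2", "H3"]}
    },
    "GLN": {
      "amide": {"atoms": ["NE2", "CD", "OE1"]}
    },
    "ASN": {
      "amide": {"atoms": ["ND2", "CG", "OD1"]}
    },
    "CYS": {
      "sulfur": {"atom": "SG"}
    },
    "MET": {
      "sulfur": {"atom": "SD"}
    },
    "MSE": {
      "sulfur": {"atom": "SE"}
    }
  },
  "nucleobases": {
    "DA": {
      "rings": [{"rings": [{"size": 6, "atoms": ["N1", "C2", "N3", "C4", "C5", "C6"]},
                            {"size": 5, "atoms": ["C4", "C5", "N7", "C8", "N9"]}],
                 "bridge": ["C4", "C5"]}],
      "base_atoms": ["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9", "N6"]
    },
    "DG": {
      "rings": [{"rings": [{"size": 6, "atoms": ["N1", "C2", "N3", "C4", "C5", "C6"]},
                            {"size": 5, "atoms": ["C4", "C5", "N7", "C8", "N9"]}],
                 "bridge": ["C4", "C5"]}],
      "base_atoms": ["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9", "O6", "N2"]
    },
    "DC": {
      "rings": [{"rings": [{"size": 6, "atoms": ["N1", "C2", "N3", "C4", "C5", "C6"]}]}],
      "base_atoms": ["N1", "C2", "N3", "C4", "C5", "C6", "O2", "N4"]
    },
    "DT": {
      "rings": [{"rings": [{"size": 6, "atoms": ["N1", "C2", "N3", "C4", "C5", "C6"]}]}],
      "base_atoms": ["N1", "C2", "N3", "C4", "C5", "C6", "O2", "O4", "C7", "C5M"]
    },
    "A": {
      "rings": [{"rings": [{"size": 6, "atoms": ["N1", "C2", "N3", "C4", "C5", "C6"]},
                            {"size": 5, "atoms": ["C4", "C5", "N7", "C8", "N9"]}],
                 "bridge": ["C4", "C5"]}],
      "base_atoms": ["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9", "N6"]
    },
    "G": {
      "rings": [{"rings": [{"size": 6, "atoms": ["N1", "C2", "N3", "C4", "C5", "C6"]},
                            {"size": 5, "atoms": ["C4", "C5", "N7", "C8", "N9"]}],
                 "bridge": ["C4", "C5"]}],
      "base_atoms": ["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9", "O6", "N2"]
    },
    "C": {
      "rings": [{"rings": [{"size": 6, "atoms": ["N1", "C2", "N3", "C4", "C5", "C6"]}]}],
      "base_atoms": ["N1", "C2", "N3", "C4", "C5", "C6", "O2", "N4"]
    },
    "U": {
      "rings": [{"rings": [{"size": 6, "atoms": ["N1", "C2", "N3", "C4", "C5", "C6"]}]}],
      "base_atoms": ["N1", "C2", "N3", "C4", "C5", "C6", "O2", "O4"]
    }
  },
  "ligands": {
    "ATP": [{"rings": [{"size": 6, "atoms": ["N1", "C2", "N3", "C4", "C5", "C6"]},
                        {"size": 5, "atoms": ["C4", "C5", "N7", "C8", "N9"]}],
             "bridge": ["C4", "C5"]}],
    "ADP": [{"rings": [{"size": 6, "atoms": ["N1", "C2", "N3", "C4", "C5", "C6"]},
                        {"size": 5, "atoms": ["C4", "C5", "N7", "C8", "N9"]}],
             "bridge": ["C4", "C5"]}],
    "AMP": [{"rings": [{"size": 6, "atoms": ["N1", "C2", "N3", "C4", "C5", "C6"]},
                        {"size": 5, "atoms": ["C4", "C5", "N7", "C8", "N9"]}],
             "bridge": ["C4", "C5"]}],
    "GTP": [{"rings": [{"size": 6, "atoms": ["N1", "C2", "N3", "C4", "C5", "C6"]},
                        {"size": 5, "atoms": ["C4", "C5", "N7", "C8", "N9"]}],
             "bridge": ["C4", "C5"]}],
    "GDP": [{"rings": [{"size": 6, "atoms": ["N1", "C2", "N3", "C4", "C5", "C6"]},
                        {"size": 5, "atoms": ["C4", "C5", "N7", "C8", "N9"]}],
             "bridge": ["C4", "C5"]}],
    "GMP": [{"rings": [{"size": 6, "atoms": ["N1", "C2", "N3", "C4", "C5", "C6"]},
                        {"size": 5, "atoms": ["C4", "C5", "N7", "C8", "N9"]}],
             "bridge": ["C4", "C5"]}],
    "SAM": [{"rings": [{"size": 6, "atoms": ["N1", "C2", "N3", "C4", "C5", "C6"]},
                        {"size": 5, "atoms": ["C4", "C5", "N7", "C8", "N9"]}],
             "bridge": ["C4", "C5"]}],
    "NAD": [{"rings": [{"size": 6, "atoms": ["N1A", "C2A", "N3A", "C4A", "C5A", "C6A"]},
                        {"size": 5, "atoms": ["C4A", "C5A", "N7A", "C8A", "N9A"]}],
             "bridge": ["C4A", "C5A"]}],
    "NDP": [{"rings": [{"size": 6, "atoms": ["N1A", "C2A", "N3A", "C4A", "C5A", "C6A"]},
                        {"size": 5, "atoms": ["C4A", "C5A", "N7A", "C8A", "N9A"]}],
             "bridge": ["C4A", "C5A"]}],
    "FAD": [{"rings": [{"size": 6, "atoms": ["N1A", "C2A", "N3A", "C4A", "C5A", "C6A"]},
                        {"size": 5, "atoms": ["C4A", "C5A", "N7A", "C8A", "N9A"]}],
             "bridge": ["C4A", "C5A"]}]
  }
}
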