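"""Heavy-atom residue templates for the 20 standard amino acids.

Each template lists sidechain heavy atoms as ``name: (element, n_hydrogens)``
and sidechain bonds as ``(atom_a, atom_b, order)`` with order ``1`` (single),
``2`` (double) or ``"ar"`` (aromatic/resonant; never rotatable).  Hydrogens
are not explicit atoms - each heavy atom carries its hydrogen count - which
is all torsion accounting needs.  Hydrogen counts assume physiological
protonation: Asp/Glu carboxylates and the Lys ammonium charged, His neutral
(epsilon tautomer), Arg guanidinium charged with resonant C-N bonds.

The backbone (N, CA, C, O, terminal OXT) is added by the topology builder,
which also adjusts terminal hydrogen counts for the chosen termini.
"""

#: sidechain heavy atoms and bonds, keyed by one-letter residue code
SIDECHAINS: dict[str, dict] = {
    "G": {"atoms": {}, "bonds": [], "aromatic": []},
    "A": {"atoms": {"CB": ("C", 3)}, "bonds": [], "aromatic": []},
    "S": {"atoms": {"CB": ("C", 2), "OG": ("O", 1)},
          "bonds": [("CB", "OG", 1)], "aromatic": []},
    "T": {"atoms": {"CB": ("C", 1), "OG1": ("O", 1), "CG2": ("C", 3)},
          "bonds": [("CB", "OG1", 1), ("CB", "CG2", 1)], "aromatic": []},
    "C": {"atoms": {"CB": ("C", 2), "SG": ("S", 1)},
          "bonds": [("CB", "SG", 1)], "aromatic": []},
    "V": {"atoms": {"CB": ("C", 1), "CG1": ("C", 3), "CG2": ("C", 3)},
          "bonds": [("CB", "CG1", 1), ("CB", "CG2", 1)], "aromatic": []},
    "L": {"atoms": {"CB": ("C", 2), "CG": ("C", 1), "CD1": ("C", 3), "CD2": ("C", 3)},
          "bonds": [("CB", "CG", 1), ("CG", "CD1", 1), ("CG", "CD2", 1)],
          "aromatic": []},
    "I": {"atoms": {"CB": ("C", 1), "CG1": ("C", 2), "CG2": ("C", 3), "CD1": ("C", 3)},
          "bonds": [("CB", "CG1", 1), ("CB", "CG2", 1), ("CG1", "CD1", 1)],
          "aromatic": []},
    "M": {"atoms": {"CB": ("C", 2), "CG": ("C", 2), "SD": ("S", 0), "CE": ("C", 3)},
          "bonds": [("CB", "CG", 1), ("CG", "SD", 1), ("SD", "CE", 1)],
          "aromatic": []},
    "P": {"atoms": {"CB": ("C", 2), "CG": ("C", 2), "CD": ("C", 2)},
          "bonds": [("CB", "CG", 1), ("CG", "CD", 1)],  # CD-N closes the ring
          "aromatic": []},
    "F": {"atoms": {"CB": ("C", 2), "CG": ("C", 0), "CD1": ("C", 1), "CD2": ("C", 1),
                    "CE1": ("C", 1), "CE2": ("C", 1), "CZ": ("C", 1)},
          "bonds": [("CB", "CG", 1), ("CG", "CD1", "ar"), ("CG", "CD2", "ar"),
                    ("CD1", "CE1", "ar"), ("CD2", "CE2", "ar"),
                    ("CE1", "CZ", "ar"), ("CE2", "CZ", "ar")],
          "aromatic": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]},
    "Y": {"atoms": {"CB": ("C", 2), "CG": ("C", 0), "CD1": ("C", 1), "CD2": ("C", 1),
                    "CE1": ("C", 1), "CE2": ("C", 1), "CZ": ("C", 0), "OH": ("O", 1)},
          "bonds": [("CB", "CG", 1), ("CG", "CD1", "ar"), ("CG", "CD2", "ar"),
                    ("CD1", "CE1", "ar"), ("CD2", "CE2", "ar"),
                    ("CE1", "CZ", "ar"), ("CE2", "CZ", "ar"), ("CZ", "OH", 1)],
          "aromatic": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]},
    "W": {"atoms": {"CB": ("C", 2), "CG": ("C", 0), "CD1": ("C", 1), "CD2": ("C", 0),
                    "NE1": ("N", 1), "CE2": ("C", 0), "CE3": ("C", 1),
                    "CZ2": ("C", 1), "CZ3": ("C", 1), "CH2": ("C", 1)},
          "bonds": [("CB", "CG", 1), ("CG", "CD1", "ar"), ("CG", "CD2", "ar"),
                    ("CD1", "NE1", "ar"), ("NE1", "CE2", "ar"),
                    ("CD2", "CE2", "ar"), ("CD2", "CE3", "ar"),
                    ("CE3", "CZ3", "ar"), ("CZ3", "CH2", "ar"),
                    ("CH2", "CZ2", "ar"), ("CZ2", "CE2", "ar")],
          "aromatic": ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"]},
    "D": {"atoms": {"CB": ("C", 2), "CG": ("C", 0), "OD1": ("O", 0), "OD2": ("O", 0)},
          "bonds": [("CB", "CG", 1), ("CG", "OD1", "ar"), ("CG", "OD2", "ar")],
          "aromatic": []},
    "E": {"atoms": {"CB": ("C", 2), "CG": ("C", 2), "CD": ("C", 0),
                    "OE1": ("O", 0), "OE2": ("O", 0)},
          "bonds": [("CB", "CG", 1), ("CG", "CD", 1),
                    ("CD", "OE1", "ar"), ("CD", "OE2", "ar")],
          "aromatic": []},
    "N": {"atoms": {"CB": ("C", 2), "CG": ("C", 0), "OD1": ("O", 0), "ND2": ("N", 2)},
          "bonds": [("CB", "CG", 1), ("CG", "OD1", 2), ("CG", "ND2", 1)],
          "aromatic": []},
    "Q": {"atoms": {"CB": ("C", 2), "CG": ("C", 2), "CD": ("C", 0),
                    "OE1": ("O", 0), "NE2": ("N", 2)},
          "bonds": [("CB", "CG", 1), ("CG", "CD", 1), ("CD", "OE1", 2),
                    ("CD", "NE2", 1)],
          "aromatic": []},
    "H": {"atoms": {"CB": ("C", 2), "CG": ("C", 0), "ND1": ("N", 0), "CD2": ("C", 1),
                    "CE1": ("C", 1), "NE2": ("N", 1)},
          "bonds": [("CB", "CG", 1), ("CG", "ND1", "ar"), ("CG", "CD2", "ar"),
                    ("ND1", "CE1", "ar"), ("CD2", "NE2", "ar"), ("CE1", "NE2", "ar")],
          "aromatic": ["CG", "ND1", "CD2", "CE1", "NE2"]},
    "K": {"atoms": {"CB": ("C", 2), "CG": ("C", 2), "CD": ("C", 2),
                    "CE": ("C", 2), "NZ": ("N", 3)},
          "bonds": [("CB", "CG", 1), ("CG", "CD", 1), ("CD", "CE", 1),
                    ("CE", "NZ", 1)],
          "aromatic": []},
    "R": {"atoms": {"CB": ("C", 2), "CG": ("C", 2), "CD": ("C", 2), "NE": ("N", 1),
                    "CZ": ("C", 0), "NH1": ("N", 2), "NH2": ("N", 2)},
          "bonds": [("CB", "CG", 1), ("CG", "CD", 1), ("CD", "NE", 1),
                    ("NE", "CZ", "ar"), ("CZ", "NH1", "ar"), ("CZ", "NH2", "ar")],
          "aromatic": []},
}

#: elements whose attached hydrogens count as polar
POLAR_HYDROGEN_HOSTS = frozenset({"N", "O", "S"})
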