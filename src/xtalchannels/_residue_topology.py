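"""Idealized topology of the 20 standard amino acids for hydrogen placement.

For every residue we record the intra-residue heavy-atom bonds and, for each
protonatable heavy atom, how many hydrogens it carries in a mid-chain residue
and whether its center is sp3 (tetrahedral completion, rotors staggered) or
sp2 (in-plane completion).  The backbone nitrogen is special-cased at run
time: with no preceding peptide carbon it is treated as a charged sp3
N-terminus (NH3+, NH2+ for proline); carboxylate oxygens (O/OXT) carry no
hydrogen.  Neutral histidine is built as the NE2-H tautomer; aspartate and
glutamate are built charged (no carboxyl hydrogen), lysine as NH3+ and
arginine as the guanidinium cation, matching the dominant states at
crystallization pH.
"""

# bond lengths to hydrogen, Angstrom
H_BOND_LENGTH = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}

BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]

# residue -> side-chain heavy-atom bonds (backbone bonds added for all)
SIDECHAIN_BONDS = {
    "ALA": [("CA", "CB")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
            ("CZ", "OH")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
}

# residue -> {heavy atom name: (hydrogen count, geometry)}
# backbone N/CA entries included; N count is the mid-chain value.
_BB = {"N": (1, "sp2"), "CA": (1, "sp3")}

HYDROGEN_COUNTS = {
    "ALA": {**_BB, "CB": (3, "sp3")},
    "ARG": {**_BB, "CB": (2, "sp3"), "CG": (2, "sp3"), "CD": (2, "sp3"),
            "NE": (1, "sp2"), "NH1": (2, "sp2"), "NH2": (2, "sp2")},
    "ASN": {**_BB, "CB": (2, "sp3"), "ND2": (2, "sp2")},
    "ASP": {**_BB, "CB": (2, "sp3")},
    "CYS": {**_BB, "CB": (2, "sp3"), "SG": (1, "sp3")},
    "GLN": {**_BB, "CB": (2, "sp3"), "CG": (2, "sp3"), "NE2": (2, "sp2")},
    "GLU": {**_BB, "CB": (2, "sp3"), "CG": (2, "sp3")},
    "GLY": {"N": (1, "sp2"), "CA": (2, "sp3")},
    "HIS": {**_BB, "CB": (2, "sp3"), "CD2": (1, "sp2"), "CE1": (1, "sp2"),
            "NE2": (1, "sp2")},
    "ILE": {**_BB, "CB": (1, "sp3"), "CG1": (2, "sp3"), "CG2": (3, "sp3"),
            "CD1": (3, "sp3")},
    "LEU": {**_BB, "CB": (2, "sp3"), "CG": (1, "sp3"), "CD1": (3, "sp3"),
            "CD2": (3, "sp3")},
    "LYS": {**_BB, "CB": (2, "sp3"), "CG": (2, "sp3"), "CD": (2, "sp3"),
            "CE": (2, "sp3"), "NZ": (3, "sp3")},
    "MET": {**_BB, "CB": (2, "sp3"), "CG": (2, "sp3"), "CE": (3, "sp3")},
    "PHE": {**_BB, "CB": (2, "sp3"), "CD1": (1, "sp2"), "CD2": (1, "sp2"),
            "CE1": (1, "sp2"), "CE2": (1, "sp2"), "CZ": (1, "sp2")},
    "PRO": {"CA": (1, "sp3"), "CB": (2, "sp3"), "CG": (2, "sp3"),
            "CD": (2, "sp3")},
    "SER": {**_BB, "CB": (2, "sp3"), "OG": (1, "sp3")},
    "THR": {**_BB, "CB": (1, "sp3"), "OG1": (1, "sp3"), "CG2": (3, "sp3")},
    "TRP": {**_BB, "CB": (2, "sp3"), "CD1": (1, "sp2"), "NE1": (1, "sp2"),
            "CE3": (1, "sp2"), "CZ2": (1, "sp2"), "CZ3": (1, "sp2"),
            "CH2": (1, "sp2")},
    "TYR": {**_BB, "CB": (2, "sp3"), "CD1": (1, "sp2"), "CD2": (1, "sp2"),
            "CE1": (1, "sp2"), "CE2": (1, "sp2"), "OH": (1, "sp3")},
    "VAL": {**_BB, "CB": (1, "sp3"), "CG1": (3, "sp3"), "CG2": (3, "sp3")},
}


def template_hydrogen_count(resname: str, n_terminal: bool = False,
                            c_terminal: bool = False) -> int:
    """Number of hydrogens the placer generates for one residue.

    ``n_terminal`` switches the backbone nitrogen to NH3+ (NH2+ for PRO);
    the C-terminus is built as a carboxylate and adds no hydrogen.
    """
    counts = HYDROGEN_COUNTS[resname]
    total = sum(n for n, _ in counts.values())
    if n_terminal:
        # NH3+ instead of the mid-chain single amide H; for PRO the ring
        # nitrogen (0 H mid-chain) becomes NH2+ — either way two more H.
        total += 2
    return total
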