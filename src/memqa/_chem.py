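"""Chemical constants: amino-acid tables, radii, atom typing, side-chain topology.

All geometry refers to heavy atoms of the 20 standard L-amino acids.
Bond lengths are in Angstrom, angles and torsions in degrees.
"""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA = tuple(sorted(THREE_TO_ONE))
AA_ONE = tuple(sorted(THREE_TO_ONE.values()))

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Van der Waals radii by element, Chothia/Naccess-style.
VDW_RADII = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85}

# Maximum accessible surface area of residue X in an extended Gly-X-Gly
# tripeptide (A^2), used to convert residue SASA to relative accessibility.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# Kyte-Doolittle hydropathy index.
HYDROPATHY = {
    "ALA": 1.8, "ARG": -4.5, "ASN": -3.5, "ASP": -3.5, "CYS": 2.5,
    "GLN": -3.5, "GLU": -3.5, "GLY": -0.4, "HIS": -3.2, "ILE": 4.5,
    "LEU": 3.8, "LYS": -3.9, "MET": 1.9, "PHE": 2.8, "PRO": -1.6,
    "SER": -0.8, "THR": -0.7, "TRP": -0.9, "TYR": -1.3, "VAL": 4.2,
}

# ---------------------------------------------------------------------------
# 13-class heavy-atom typing used for atom-atom contact features.

ATOM_CLASSES = (
    "C_ali",    # aliphatic carbon
    "C_aro",    # aromatic ring carbon
    "C_car",    # carbonyl / carboxamide carbon
    "C_cox",    # carboxylate carbon
    "C_gua",    # guanidinium carbon (ARG CZ)
    "C_alpha",  # alpha carbon
    "N_ami",    # backbone and side-chain amide nitrogen
    "N_pos",    # positively chargeable nitrogen
    "N_aro",    # aromatic ring NH (TRP NE1)
    "O_hyd",    # hydroxyl oxygen
    "O_car",    # carbonyl oxygen
    "O_cox",    # carboxylate oxygen
    "S",        # sulfur
)

_AROMATIC_C = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "CD2", "CE1"},
}


def atom_class(aa_type: str, atom_name: str) -> str:
    """Map a heavy atom to one of the 13 contact classes."""
    name = atom_name
    if name.startswith("S"):
        return "S"
    if name.startswith("O"):
        if name in ("O", "OXT"):
            return "O_car"
        if aa_type in ("ASN", "GLN") and name in ("OD1", "OE1"):
            return "O_car"
        if aa_type in ("ASP", "GLU") and name in ("OD1", "OD2", "OE1", "OE2"):
            return "O_cox"
        return "O_hyd"  # SER OG, THR OG1, TYR OH
    if name.startswith("N"):
        if name == "N":
            return "N_ami"
        if aa_type == "ASN" and name == "ND2":
            return "N_ami"
        if aa_type == "GLN" and name == "NE2":
            return "N_ami"
        if aa_type == "TRP" and name == "NE1":
            return "N_aro"
        return "N_pos"  # LYS NZ, ARG NE/NH1/NH2, HIS ND1/NE2
    # carbon
    if name == "CA":
        return "C_alpha"
    if name == "C":
        return "C_car"
    if aa_type in ("ASN",) and name == "CG":
        return "C_car"
    if aa_type in ("GLN",) and name == "CD":
        return "C_car"
    if aa_type == "ASP" and name == "CG":
        return "C_cox"
    if aa_type == "GLU" and name == "CD":
        return "C_cox"
    if aa_type == "ARG" and name == "CZ":
        return "C_gua"
    if aa_type in _AROMATIC_C and name in _AROMATIC_C[aa_type]:
        return "C_aro"
    return "C_ali"


def element_of(atom_name: str) -> str:
    """Infer the element from a PDB atom name (heavy atoms and hydrogens)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    first = stripped[0].upper()
    if first in ("H", "D"):
        return "H"
    return first


# ---------------------------------------------------------------------------
# Chi dihedral definitions: ordered heavy-atom quadruplets per residue type.

_CHI1 = ("N", "CA", "CB", "CG")

CHI_ATOMS: dict[str, tuple[tuple[str, str, str, str], ...]] = {
    "ALA": (),
    "GLY": (),
    "ARG": (_CHI1, ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "NE"),
            ("CG", "CD", "NE", "CZ")),
    "ASN": (_CHI1, ("CA", "CB", "CG", "OD1")),
    "ASP": (_CHI1, ("CA", "CB", "CG", "OD1")),
    "CYS": (("N", "CA", "CB", "SG"),),
    "GLN": (_CHI1, ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")),
    "GLU": (_CHI1, ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")),
    "HIS": (_CHI1, ("CA", "CB", "CG", "ND1")),
    "ILE": (("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")),
    "LEU": (_CHI1, ("CA", "CB", "CG", "CD1")),
    "LYS": (_CHI1, ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "CE"),
            ("CG", "CD", "CE", "NZ")),
    "MET": (_CHI1, ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")),
    "PHE": (_CHI1, ("CA", "CB", "CG", "CD1")),
    "PRO": (_CHI1, ("CA", "CB", "CG", "CD")),
    "SER": (("N", "CA", "CB", "OG"),),
    "THR": (("N", "CA", "CB", "OG1"),),
    "TRP": (_CHI1, ("CA", "CB", "CG", "CD1")),
    "TYR": (_CHI1, ("CA", "CB", "CG", "CD1")),
    "VAL": (("N", "CA", "CB", "CG1"),),
}

# Chi angles whose terminal group is two-fold symmetric (value ambiguous
# modulo 180 degrees).  Keys are residue types, values 0-based chi indices.
CHI_SYMMETRIC: dict[str, frozenset[int]] = {
    "ASP": frozenset({1}),
    "GLU": frozenset({2}),
    "PHE": frozenset({1}),
    "TYR": frozenset({1}),
}

# ---------------------------------------------------------------------------
# Side-chain build topology.  Each entry places one heavy atom by internal
# coordinates (NeRF) from three previously known atoms (a, b, c): bond length
# |c-new|, bond angle b-c-new, and torsion a-b-c-new.  A torsion is either a
# fixed float or ("chi", i, offset) meaning chi_i + offset.

Torsion = float | tuple[str, int, float]
TopoEntry = tuple[str, tuple[str, str, str], float, float, Torsion]

_CB: TopoEntry = ("CB", ("C", "N", "CA"), 1.53, 110.4, 120.5)


def _chi(i: int, offset: float = 0.0) -> Torsion:
    return ("chi", i, offset)


SIDECHAIN_TOPOLOGY: dict[str, tuple[TopoEntry, ...]] = {
    "ALA": (_CB,),
    "GLY": (),
    "ARG": (
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, _chi(0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, _chi(1)),
        ("NE", ("CB", "CG", "CD"), 1.46, 112.0, _chi(2)),
        ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, _chi(3)),
        ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0),
    ),
    "ASN": (
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 112.6, _chi(0)),
        ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, _chi(1)),
        ("ND2", ("CA", "CB", "CG"), 1.33, 116.5, _chi(1, 180.0)),
    ),
    "ASP": (
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 112.6, _chi(0)),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118.5, _chi(1)),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118.5, _chi(1, 180.0)),
    ),
    "CYS": (
        _CB,
        ("SG", ("N", "CA", "CB"), 1.81, 114.4, _chi(0)),
    ),
    "GLN": (
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, _chi(0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, _chi(1)),
        ("OE1", ("CB", "CG", "CD"), 1.23, 120.8, _chi(2)),
        ("NE2", ("CB", "CG", "CD"), 1.33, 116.5, _chi(2, 180.0)),
    ),
    "GLU": (
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, _chi(0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, _chi(1)),
        ("OE1", ("CB", "CG", "CD"), 1.25, 118.5, _chi(2)),
        ("OE2", ("CB", "CG", "CD"), 1.25, 118.5, _chi(2, 180.0)),
    ),
    "HIS": (
        _CB,
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, _chi(0)),
        ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, _chi(1)),
        ("CD2", ("CA", "CB", "CG"), 1.36, 131.1, _chi(1, 180.0)),
        ("CE1", ("CB", "CG", "ND1"), 1.32, 109.3, 180.0),
        ("NE2", ("CB", "CG", "CD2"), 1.37, 107.2, 180.0),
    ),
    "ILE": (
        _CB,
        ("CG1", ("N", "CA", "CB"), 1.53, 110.4, _chi(0)),
        ("CG2", ("N", "CA", "CB"), 1.53, 110.5, _chi(0, 120.0)),
        ("CD1", ("CA", "CB", "CG1"), 1.52, 113.9, _chi(1)),
    ),
    "LEU": (
        _CB,
        ("CG", ("N", "CA", "CB"), 1.53, 116.3, _chi(0)),
        ("CD1", ("CA", "CB", "CG"), 1.52, 110.5, _chi(1)),
        ("CD2", ("CA", "CB", "CG"), 1.52, 110.5, _chi(1, -120.0)),
    ),
    "LYS": (
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, _chi(0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, _chi(1)),
        ("CE", ("CB", "CG", "CD"), 1.52, 111.3, _chi(2)),
        ("NZ", ("CG", "CD", "CE"), 1.49, 112.0, _chi(3)),
    ),
    "MET": (
        _CB,
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, _chi(0)),
        ("SD", ("CA", "CB", "CG"), 1.81, 112.7, _chi(1)),
        ("CE", ("CB", "CG", "SD"), 1.79, 100.8, _chi(2)),
    ),
    "PHE": (
        _CB,
        ("CG", ("N", "CA", "CB"), 1.50, 113.9, _chi(0)),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, _chi(1)),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, _chi(1, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.8, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.8, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ),
    "PRO": (
        _CB,
        ("CG", ("N", "CA", "CB"), 1.50, 104.5, _chi(0)),
        ("CD", ("CA", "CB", "CG"), 1.51, 105.5, _chi(1)),
    ),
    "SER": (
        _CB,
        ("OG", ("N", "CA", "CB"), 1.42, 111.1, _chi(0)),
    ),
    "THR": (
        _CB,
        ("OG1", ("N", "CA", "CB"), 1.43, 109.6, _chi(0)),
        ("CG2", ("N", "CA", "CB"), 1.52, 110.5, _chi(0, 120.0)),
    ),
    "TRP": (
        _CB,
        ("CG", ("N", "CA", "CB"), 1.50, 113.7, _chi(0)),
        ("CD1", ("CA", "CB", "CG"), 1.37, 127.0, _chi(1)),
        ("CD2", ("CA", "CB", "CG"), 1.43, 126.6, _chi(1, 180.0)),
        ("NE1", ("CB", "CG", "CD1"), 1.38, 110.1, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.41, 107.3, 180.0),
        ("CE3", ("CB", "CG", "CD2"), 1.40, 133.9, 0.0),
        ("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.3, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.7, 180.0),
        ("CH2", ("CD2", "CE3", "CZ3"), 1.37, 121.2, 0.0),
    ),
    "TYR": (
        _CB,
        ("CG", ("N", "CA", "CB"), 1.51, 113.9, _chi(0)),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, _chi(1)),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, _chi(1, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 121.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 121.2, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.38, 119.6, 0.0),
        ("OH", ("CD1", "CE1", "CZ"), 1.38, 119.9, 180.0),
    ),
    "VAL": (
        _CB,
        ("CG1", ("N", "CA", "CB"), 1.53, 110.5, _chi(0)),
        ("CG2", ("N", "CA", "CB"), 1.53, 110.5, _chi(0, -120.0)),
    ),
}

# Backbone ideal internal geometry (Engh-Huber-style averages).
BB_N_CA = 1.458
BB_CA_C = 1.525
BB_C_N = 1.329
BB_C_O = 1.231
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.8
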