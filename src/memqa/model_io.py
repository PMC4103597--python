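"""Reading, writing and validating all-atom protein models in PDB format.

Dialect rules, applied deterministically so downstream features never depend
on parser ambiguity:

* only the first ``MODEL`` block of a multi-model file is read;
* ``HETATM`` records are ignored;
* alternate locations are resolved by keeping the highest-occupancy copy
  (ties: first seen);
* hydrogens are parsed and flagged but excluded from every feature and
  energy computation;
* residues with non-standard types are dropped with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._chem import BACKBONE_ATOMS, STANDARD_AA, THREE_TO_ONE, element_of

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "extract_sequence",
    "validate_model",
]


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    temp_factor: float = 0.0
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    seq_number: int
    insertion_code: str
    aa_type: str  # three-letter code, one of the 20 standard amino acids
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.aa_type not in STANDARD_AA:
            raise ValueError(f"non-standard residue type {self.aa_type!r}")

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE[self.aa_type]

    @property
    def res_id(self) -> tuple[int, str]:
        return (self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.coord

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def has_backbone(self) -> bool:
        names = {a.name for a in self.atoms}
        return all(n in names for n in BACKBONE_ATOMS)


@dataclass
class StructureModel:
    target_id: str
    model_id: str
    chains: list[tuple[str, list[Residue]]]

    def __post_init__(self) -> None:
        if not any(res for _, res in self.chains):
            raise ValueError("model must contain at least one residue")

    def residues(self) -> list[Residue]:
        """All residues in chain order."""
        return [r for _, chain in self.chains for r in chain]

    def chain_index(self) -> list[int]:
        """Chain ordinal for each residue, aligned with :meth:`residues`."""
        return [i for i, (_, chain) in enumerate(self.chains) for _ in chain]

    def residue_keys(self) -> list[tuple[str, int, str]]:
        return [(cid, r.seq_number, r.insertion_code)
                for cid, chain in self.chains for r in chain]

    def n_residues(self) -> int:
        return sum(len(chain) for _, chain in self.chains)

    def heavy_coords(self) -> tuple[np.ndarray, list[tuple[int, Atom]]]:
        """Stacked heavy-atom coordinates plus (residue index, atom) owners."""
        owners: list[tuple[int, Atom]] = []
        for i, res in enumerate(self.residues()):
            for a in res.heavy_atoms():
                owners.append((i, a))
        coords = np.array([a.coord for _, a in owners], dtype=float)
        return coords, owners

    def copy(self) -> "StructureModel":
        chains = [
            (cid, [replace(r, atoms=[replace(a, coord=a.coord.copy()) for a in r.atoms])
                   for r in chain])
            for cid, chain in self.chains
        ]
        return StructureModel(self.target_id, self.model_id, chains)


def read_pdb(path, target_id: str = "", model_id: str = "") -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Only ``ATOM`` records of the first ``MODEL`` block are used; see module
    docstring for the full dialect.
    """
    path = str(path)
    # raw[(chain, seqnum, icode)] -> {atom name: list of candidate atoms}
    raw: dict[tuple[str, int, str], dict] = {}
    in_model = 0
    seen_model_end = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                in_model += 1
                if in_model > 1 or seen_model_end:
                    break
                continue
            if rec == "ENDMDL":
                seen_model_end = True
                continue
            if seen_model_end:
                continue
            if rec != "ATOM  ":
                continue
            line = line.rstrip("\n")
            try:
                name = line[12:16].strip()
                altloc = line[16]
                resname = line[17:20].strip()
                chain_id = line[21]
                seq_number = int(line[22:26])
                icode = line[26] if len(line) > 26 else " "
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise PDBParseError(f"{path}: malformed ATOM record at line {lineno}: {exc}") from exc
            occ = _float_or(line[54:60], 1.0)
            bfac = _float_or(line[60:66], 0.0)
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = element_of(name)
            key = (chain_id, seq_number, icode)
            raw.setdefault(key, {"resname": resname, "atoms": {}})
            raw[key]["atoms"].setdefault(name, []).append(
                (occ, altloc, Atom(name, element.upper(), np.array([x, y, z]),
                                   occ, bfac, element.upper() == "H"))
            )
    if not raw:
        raise PDBParseError(f"{path}: no ATOM records found")

    chains: dict[str, list[Residue]] = {}
    for (chain_id, seq_number, icode), entry in raw.items():
        resname = entry["resname"]
        if resname not in STANDARD_AA:
            logger.warning("%s: dropping non-standard residue %s %s%d%s",
                           path, resname, chain_id, seq_number, icode.strip())
            continue
        atoms = []
        for name, candidates in entry["atoms"].items():
            # altloc resolution: highest occupancy, ties -> first seen
            best = max(candidates, key=lambda c: c[0])
            atoms.append(best[2])
        chains.setdefault(chain_id, []).append(
            Residue(seq_number, icode, resname, atoms))
    if not chains:
        raise PDBParseError(f"{path}: no standard amino-acid residues found")
    ordered = []
    for chain_id, residues in chains.items():
        residues.sort(key=lambda r: (r.seq_number, r.insertion_code))
        ordered.append((chain_id, residues))
    import os
    base = os.path.splitext(os.path.basename(path))[0]
    return StructureModel(target_id or base, model_id or base, ordered)


def _float_or(text: str, default: float) -> float:
    text = text.strip()
    if not text:
        return default
    try:
        return float(text)
    except ValueError:
        return default


def write_pdb(model: StructureModel, path) -> None:
    """Write ``ATOM`` records (8.3 coordinates), one ``TER`` per chain, ``END``."""
    lines = []
    serial = 1
    for chain_id, residues in model.chains:
        last = None
        for res in residues:
            for atom in res.atoms:
                name = atom.name
                # columns 13-16: element right-justified into columns 13-14
                if len(name) < 4:
                    name_field = f" {name:<3s}"
                else:
                    name_field = name[:4]
                lines.append(
                    f"ATOM  {serial:5d} {name_field} {res.aa_type:>3s} {chain_id}"
                    f"{res.seq_number:4d}{res.insertion_code}   "
                    f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
                    f"{atom.occupancy:6.2f}{atom.temp_factor:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
            last = res
        if last is not None:
            lines.append(
                f"TER   {serial:5d}      {last.aa_type:>3s} {chain_id}"
                f"{last.seq_number:4d}{last.insertion_code}"
            )
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def extract_sequence(model: StructureModel) -> list[str]:
    """One-letter amino-acid string per chain, chain order preserved."""
    return ["".join(r.one_letter for r in chain) for _, chain in model.chains]


def validate_model(model: StructureModel, break_distance: float = 2.5) -> list[dict]:
    """Report structural issues; an empty list means the model is clean.

    Checks: residues missing any backbone atom; chain breaks (consecutive
    C-N distance above ``break_distance``); duplicate residue identifiers.
    """
    issues: list[dict] = []
    for chain_id, residues in model.chains:
        seen = set()
        for res in residues:
            rid = (chain_id, res.seq_number, res.insertion_code)
            if rid in seen:
                issues.append({"kind": "duplicate_residue", "residue": rid})
            seen.add(rid)
            missing = [n for n in BACKBONE_ATOMS if res.atom(n) is None]
            if missing:
                issues.append({"kind": "missing_backbone", "residue": rid,
                               "atoms": missing})
        for prev, nxt in zip(residues, residues[1:]):
            c = prev.coord("C")
            n = nxt.coord("N")
            if c is None or n is None:
                continue
            d = float(np.linalg.norm(c - n))
            if d > break_distance:
                issues.append({
                    "kind": "chain_break",
                    "residue": (chain_id, nxt.seq_number, nxt.insertion_code),
                    "distance": d,
                })
    return issues
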