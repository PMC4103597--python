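"""Fixed-backbone side-chain resampling.

Side chains are rebuilt from a backbone-dependent rotamer library under a
simplified packing energy with three additive terms: a soft-sphere steric
clash penalty, a rotamer log-probability term, and a membrane
hydropathy-mismatch term.  Repacking sweeps residues in seeded random order
and greedily accepts the lowest-energy rotamer per residue; the backbone
(N, CA, C, O) is never touched, so CA-based quality measures such as the
TM-score are exactly invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from ._chem import (BACKBONE_ATOMS, CHI_ATOMS, HYDROPATHY, SIDECHAIN_TOPOLOGY,
                    STANDARD_AA, VDW_RADII, element_of)
from .features import MembraneSpec, membrane_depth
from .geometry_eval import circular_difference, dihedral
from .model_io import Atom, Residue, StructureModel

__all__ = [
    "Rotamer",
    "RotamerLibrary",
    "PackingParams",
    "RepackResult",
    "builtin_library",
    "read_rotamer_library",
    "write_rotamer_library",
    "backbone_dihedrals",
    "place_side_chain",
    "packing_energy",
    "repack",
    "generate_decoys",
]

try:
    from numba import njit as _njit

    @_njit(cache=False)
    def _steric_per_candidate(flat, flat_r, ncand, other, other_r,
                              center, reach, scale):
        m = flat.shape[0]
        k = m // ncand if ncand else 0
        out = np.zeros(ncand)
        n = other.shape[0]
        rmax = 0.0
        for j in range(n):
            if other_r[j] > rmax:
                rmax = other_r[j]
        margin = reach + 2.0 * scale * rmax
        m2 = margin * margin
        for j in range(n):
            dxc = other[j, 0] - center[0]
            dyc = other[j, 1] - center[1]
            dzc = other[j, 2] - center[2]
            if dxc * dxc + dyc * dyc + dzc * dzc >= m2:
                continue
            for t in range(m):
                thr = scale * (flat_r[t] + other_r[j])
                dx = flat[t, 0] - other[j, 0]
                dy = flat[t, 1] - other[j, 1]
                dz = flat[t, 2] - other[j, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < thr * thr:
                    ov = thr - np.sqrt(d2)
                    out[t // k] += ov * ov
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

ROTLIB_HEADER = "# MEMQA-ROTLIB v1"
_MIN_ROT_PROB = 1e-3
_BIN_WIDTH = 30.0
_N_BINS = 12


@dataclass(frozen=True)
class Rotamer:
    chis: tuple          # mean chi angles, degrees
    sds: tuple           # standard deviations, degrees
    prob: float


@dataclass
class RotamerLibrary:
    """Rotamers per residue type and 30-degree (phi, psi) bin.

    ``fallback`` holds backbone-independent entries used for unpopulated
    bins and for residues with undefined phi/psi (chain termini).
    """

    entries: dict = field(default_factory=dict)   # (aa, pbin, qbin) -> [Rotamer]
    fallback: dict = field(default_factory=dict)  # aa -> [Rotamer]

    @staticmethod
    def bin_of(angle: float) -> int:
        b = int((angle + 180.0) // _BIN_WIDTH)
        return min(max(b, 0), _N_BINS - 1)

    def add(self, aa: str, pbin, qbin, rotamers) -> None:
        rotamers = _normalized(rotamers)
        if pbin is None or qbin is None:
            self.fallback[aa] = rotamers
        else:
            self.entries[(aa, pbin, qbin)] = rotamers

    def get(self, aa: str, phi: float | None, psi: float | None):
        if phi is not None and psi is not None:
            key = (aa, self.bin_of(phi), self.bin_of(psi))
            if key in self.entries:
                return self.entries[key]
        if aa not in self.fallback:
            raise KeyError(f"no rotamers for residue type {aa!r}")
        return self.fallback[aa]

    def most_probable(self, aa: str, phi, psi) -> Rotamer:
        return max(self.get(aa, phi, psi), key=lambda r: r.prob)

    def nearest(self, aa: str, phi, psi, chis) -> Rotamer:
        """Library rotamer closest to the given chi angles (max circular gap)."""
        rots = self.get(aa, phi, psi)

        def dist(rot: Rotamer) -> float:
            gaps = [circular_difference(c, m)
                    for c, m in zip(chis, rot.chis) if c is not None]
            return max(gaps) if gaps else 0.0

        return min(rots, key=lambda r: (dist(r), -r.prob))


def _normalized(rotamers):
    total = sum(r.prob for r in rotamers)
    if total <= 0:
        raise ValueError("rotamer probabilities must be positive")
    return [replace_prob(r, r.prob / total) for r in rotamers]


def replace_prob(r: Rotamer, p: float) -> Rotamer:
    return Rotamer(r.chis, r.sds, p)


@dataclass
class PackingParams:
    steric_weight: float = 1.0
    rotamer_weight: float = 0.2
    membrane_weight: float = 0.1
    clash_scale: float = 0.8   # fraction of summed vdW radii where penalty starts
    max_sweeps: int = 10
    jitter_sd_scale: float = 0.0  # >0 draws chis ~ N(mean, scale * library sd)
    anneal: bool = False       # Metropolis sweeps with a seeded temperature
    anneal_t_start: float = 2.0  # schedule instead of pure greedy descent
    anneal_t_end: float = 0.05

    def __post_init__(self) -> None:
        if min(self.steric_weight, self.rotamer_weight, self.membrane_weight) < 0:
            raise ValueError("weights must be non-negative")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")


@dataclass
class RepackResult:
    model: StructureModel
    final_energy: float
    energy_trace: list   # [input, after initialization, after each sweep]
    seed: int


# ---------------------------------------------------------------------------
# built-in rotamer library

# chi-state tables: per residue type a list per chi of (mean, probability).
_CHI1_GENERAL = [(-65.0, 0.52), (180.0, 0.33), (62.0, 0.15)]
_CHI2_SP3 = [(180.0, 0.60), (-65.0, 0.25), (65.0, 0.15)]

_CHI_STATES: dict[str, list] = {
    "ARG": [_CHI1_GENERAL, _CHI2_SP3, [(180.0, 1.0)], [(180.0, 1.0)]],
    "ASN": [_CHI1_GENERAL, [(-40.0, 0.4), (60.0, 0.3), (180.0, 0.3)]],
    "ASP": [_CHI1_GENERAL, [(-15.0, 0.6), (65.0, 0.4)]],
    "CYS": [_CHI1_GENERAL],
    "GLN": [_CHI1_GENERAL, _CHI2_SP3, [(0.0, 1.0)]],
    "GLU": [_CHI1_GENERAL, _CHI2_SP3, [(-10.0, 1.0)]],
    "HIS": [_CHI1_GENERAL, [(-75.0, 0.5), (75.0, 0.5)]],
    "ILE": [[(-65.0, 0.60), (180.0, 0.25), (62.0, 0.15)],
            [(170.0, 0.7), (65.0, 0.3)]],
    "LEU": [[(-65.0, 0.60), (180.0, 0.35), (62.0, 0.05)],
            [(175.0, 0.65), (65.0, 0.35)]],
    "LYS": [_CHI1_GENERAL, _CHI2_SP3, [(180.0, 1.0)], [(180.0, 1.0)]],
    "MET": [_CHI1_GENERAL, [(180.0, 0.5), (-65.0, 0.3), (65.0, 0.2)],
            [(180.0, 1.0)]],
    "PHE": [_CHI1_GENERAL, [(90.0, 0.5), (-90.0, 0.5)]],
    "SER": [_CHI1_GENERAL],
    "THR": [_CHI1_GENERAL],
    "TRP": [_CHI1_GENERAL, [(95.0, 0.5), (-95.0, 0.5)]],
    "TYR": [_CHI1_GENERAL, [(90.0, 0.5), (-90.0, 0.5)]],
    "VAL": [[(175.0, 0.70), (-60.0, 0.20), (63.0, 0.10)]],
}

# helix and sheet backbone regions get a shifted chi1 preference
_CHI1_HELIX = [(-65.0, 0.75), (180.0, 0.20), (62.0, 0.05)]
_CHI1_SHEET = [(-65.0, 0.40), (180.0, 0.50), (62.0, 0.10)]
_HELIX_REGION = ((-100.0, -30.0), (-80.0, -20.0))   # (phi range, psi range)
_SHEET_REGION = ((-150.0, -90.0), (90.0, 150.0))
_CHI_SD = 8.0


def _cross(states) -> list:
    rots = [Rotamer((), (), 1.0)]
    for per_chi in states:
        rots = [Rotamer(r.chis + (mean,), r.sds + (_CHI_SD,), r.prob * p)
                for r in rots for mean, p in per_chi]
    return rots


def builtin_library() -> RotamerLibrary:
    """Minimal backbone-dependent rotamer library.

    Backbone-independent rotamers are crossed from per-chi canonical states;
    helix- and sheet-region (phi, psi) bins re-weight the chi1 preference.
    Proline uses its two correlated ring-pucker rotamers.
    """
    lib = RotamerLibrary()
    for aa, states in _CHI_STATES.items():
        lib.add(aa, None, None, _cross(states))
    lib.add("PRO", None, None, [
        Rotamer((-25.0, 35.0), (6.0, 6.0), 0.5),
        Rotamer((25.0, -35.0), (6.0, 6.0), 0.5),
    ])
    for region, chi1 in ((_HELIX_REGION, _CHI1_HELIX), (_SHEET_REGION, _CHI1_SHEET)):
        (plo, phi_hi), (qlo, qhi) = region
        pbins = range(RotamerLibrary.bin_of(plo), RotamerLibrary.bin_of(phi_hi - 1e-9) + 1)
        qbins = range(RotamerLibrary.bin_of(qlo), RotamerLibrary.bin_of(qhi - 1e-9) + 1)
        for aa, states in _CHI_STATES.items():
            if states[0] is not _CHI1_GENERAL:
                continue
            biased = _cross([chi1] + states[1:])
            for pb in pbins:
                for qb in qbins:
                    lib.add(aa, pb, qb, biased)
    return lib


@lru_cache(maxsize=1)
def _default_library() -> RotamerLibrary:
    return builtin_library()


def write_rotamer_library(lib: RotamerLibrary, path) -> None:
    with open(path, "w") as fh:
        fh.write(ROTLIB_HEADER + "\n")
        fh.write("aa\tphi_bin\tpsi_bin\tchi_means\tchi_sds\tprob\n")

        def fmt(aa, pbin, qbin, rot):
            means = ",".join(f"{c:.2f}" for c in rot.chis)
            sds = ",".join(f"{s:.2f}" for s in rot.sds)
            return f"{aa}\t{pbin}\t{qbin}\t{means}\t{sds}\t{rot.prob:.6f}\n"

        for aa in sorted(lib.fallback):
            for rot in lib.fallback[aa]:
                fh.write(fmt(aa, "*", "*", rot))
        for (aa, pb, qb) in sorted(lib.entries):
            for rot in lib.entries[(aa, pb, qb)]:
                fh.write(fmt(aa, pb, qb, rot))


def read_rotamer_library(path) -> RotamerLibrary:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != ROTLIB_HEADER:
        raise ValueError(f"{path}: not a {ROTLIB_HEADER!r} file")
    groups: dict = {}
    for ln in lines[1:]:
        if not ln or ln.startswith("#") or ln.startswith("aa\t"):
            continue
        aa, pb, qb, means, sds, prob = ln.split("\t")
        key = (aa, None if pb == "*" else int(pb), None if qb == "*" else int(qb))
        chis = tuple(float(v) for v in means.split(",")) if means else ()
        sdt = tuple(float(v) for v in sds.split(",")) if sds else ()
        groups.setdefault(key, []).append(Rotamer(chis, sdt, float(prob)))
    lib = RotamerLibrary()
    for (aa, pb, qb), rots in groups.items():
        lib.add(aa, pb, qb, rots)
    return lib


# ---------------------------------------------------------------------------
# backbone dihedrals and side-chain construction

def backbone_dihedrals(model: StructureModel):
    """Per-residue (phi, psi) in degrees; ``None`` where undefined (termini)."""
    out = []
    for _, chain in model.chains:
        for i, res in enumerate(chain):
            phi = psi = None
            n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
            if n is not None and ca is not None and c is not None:
                if i > 0:
                    c_prev = chain[i - 1].coord("C")
                    if c_prev is not None:
                        try:
                            phi = dihedral(c_prev, n, ca, c)
                        except ValueError:  # degenerate backbone geometry
                            phi = None
                if i + 1 < len(chain):
                    n_next = chain[i + 1].coord("N")
                    if n_next is not None:
                        try:
                            psi = dihedral(n, ca, c, n_next)
                        except ValueError:
                            psi = None
            out.append((phi, psi))
    return out


def _place_candidates(aa_type: str, bb_n, bb_ca, bb_c, chi_sets: np.ndarray):
    """Build side-chain heavy atoms for many chi sets at once.

    ``chi_sets`` is (n_candidates, n_chi); returns (atom names,
    coordinates of shape (n_candidates, n_atoms, 3)).
    """
    topo = SIDECHAIN_TOPOLOGY[aa_type]
    ncand = chi_sets.shape[0]
    placed = {
        "N": np.broadcast_to(bb_n, (ncand, 3)),
        "CA": np.broadcast_to(bb_ca, (ncand, 3)),
        "C": np.broadcast_to(bb_c, (ncand, 3)),
    }
    names = []
    coords = np.empty((ncand, len(topo), 3))
    for k, (name, (ra, rb, rc), bond, angle, torsion) in enumerate(topo):
        if isinstance(torsion, tuple):
            _, idx, offset = torsion
            tor = chi_sets[:, idx] + offset
        else:
            tor = np.full(ncand, torsion)
        a, b, c = placed[ra], placed[rb], placed[rc]
        coords[:, k, :] = _nerf_batch(a, b, c, bond, angle, tor)
        placed[name] = coords[:, k, :]
        names.append(name)
    return names, coords


def _nerf_batch(a, b, c, bond: float, angle: float, torsion) -> np.ndarray:
    ang = np.radians(angle)
    tor = np.radians(np.asarray(torsion, dtype=float))
    sa = bond * np.sin(ang)
    d_local = np.stack([
        np.full_like(tor, -bond * np.cos(ang)),
        sa * np.cos(tor),
        -sa * np.sin(tor),
    ], axis=1)
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=1, keepdims=True)
    ab = b - a
    n = _cross_rows(ab, bc)
    n = n / np.linalg.norm(n, axis=1, keepdims=True)
    m = _cross_rows(n, bc)
    # rotation columns (bc, m, n) applied to d_local
    return (c + bc * d_local[:, :1] + m * d_local[:, 1:2] + n * d_local[:, 2:3])


def _cross_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def place_side_chain(residue_type: str, backbone: dict, chis) -> dict:
    """Place side-chain heavy atoms (including CB) from chi angles.

    ``backbone`` maps "N"/"CA"/"C" to coordinates.  The chi count must match
    the residue type; measuring the chi angles of the placed atoms recovers
    the inputs.
    """
    if residue_type not in STANDARD_AA:
        raise ValueError(f"unknown residue type {residue_type!r}")
    expected = len(CHI_ATOMS[residue_type])
    chis = tuple(float(c) for c in chis)
    if len(chis) != expected:
        raise ValueError(
            f"{residue_type} takes {expected} chi angles, got {len(chis)}")
    chi_arr = np.asarray(chis, dtype=float).reshape(1, -1) if expected \
        else np.zeros((1, 0))
    names, coords = _place_candidates(
        residue_type, np.asarray(backbone["N"], dtype=float),
        np.asarray(backbone["CA"], dtype=float),
        np.asarray(backbone["C"], dtype=float), chi_arr)
    return {name: coords[0, k].copy() for k, name in enumerate(names)}


# ---------------------------------------------------------------------------
# packing energy

def _steric_pair_energy(d, r_sum, scale):
    overlap = np.maximum(0.0, scale * r_sum - d)
    return overlap * overlap


def packing_energy(model: StructureModel, params: PackingParams | None = None,
                   spec: MembraneSpec | None = None) -> float:
    """Simplified additive packing energy (arbitrary units).

    steric: sum over inter-residue heavy-atom pairs involving at least one
    side-chain atom of ``max(0, s (r_i + r_j) - d)^2`` (pairs between
    covalently constrained CB/backbone atoms of adjacent residues excluded);
    rotamer: ``-ln p`` of the nearest library rotamer per residue;
    membrane: hydropathy mismatch between residue type and membrane region.
    """
    if params is None:
        params = PackingParams()
    if spec is None:
        spec = MembraneSpec()
    lib = _default_library()
    coords, owners = model.heavy_coords()
    n_atoms = len(owners)
    radii = np.array([VDW_RADII[a.element] for _, a in owners])
    owner = np.array([ri for ri, _ in owners])
    is_bbcb = np.array([a.name in BACKBONE_ATOMS or a.name == "CB"
                        for _, a in owners])
    is_bb = np.array([a.name in BACKBONE_ATOMS for _, a in owners])
    chain_idx = np.asarray(model.chain_index())

    steric = 0.0
    if n_atoms > 1:
        from scipy.spatial import cKDTree
        tree = cKDTree(coords)
        reach = params.clash_scale * 2.0 * radii.max()
        pairs = tree.query_pairs(reach, output_type="ndarray")
        if len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            keep = owner[i] != owner[j]
            keep &= ~(is_bb[i] & is_bb[j])
            adjacent = (chain_idx[owner[i]] == chain_idx[owner[j]]) & \
                (np.abs(owner[i] - owner[j]) == 1)
            keep &= ~(adjacent & is_bbcb[i] & is_bbcb[j])
            i, j = i[keep], j[keep]
            d = np.linalg.norm(coords[i] - coords[j], axis=1)
            steric = float(_steric_pair_energy(d, radii[i] + radii[j],
                                               params.clash_scale).sum())

    rot_energy = 0.0
    dihedrals = backbone_dihedrals(model)
    from .geometry_eval import compute_chi_angles
    for res, (phi, psi) in zip(model.residues(), dihedrals):
        if not CHI_ATOMS[res.aa_type]:
            continue
        rec = compute_chi_angles(res)
        if all(c is None for c in rec.chi):
            continue
        rot = lib.nearest(res.aa_type, phi, psi, rec.chi)
        rot_energy += -np.log(max(rot.prob, _MIN_ROT_PROB))

    mem_energy = 0.0
    _, regions = membrane_depth(model, spec)
    for res, region in zip(model.residues(), regions):
        mem_energy += _hydropathy_mismatch(res.aa_type, region)

    return (params.steric_weight * steric
            + params.rotamer_weight * rot_energy
            + params.membrane_weight * mem_energy)


def _hydropathy_mismatch(aa_type: str, region: str) -> float:
    hp = HYDROPATHY[aa_type] / 4.5  # normalize to [-1, 1]
    if region == "core":
        return max(0.0, -hp)
    if region == "water":
        return max(0.0, hp)
    return 0.0


# ---------------------------------------------------------------------------
# repacking

class _RepackContext:
    """Per-model precomputation shared by all repack seeds of one backbone.

    Candidate rotamer placements depend only on the fixed backbone and the
    library, so for a decoy series they are built once; each seeded run
    only permutes sweep order and mutates a private coordinate array.
    """

    def __init__(self, model: StructureModel, library: RotamerLibrary,
                 params: PackingParams, spec: MembraneSpec,
                 rng: np.random.Generator | None = None):
        self.model = model
        self.params = params
        self.spec = spec
        self.e_input = packing_energy(model, params, spec)
        residues = model.residues()
        self.chain_idx = np.asarray(model.chain_index())
        dihedrals = backbone_dihedrals(model)

        active = []
        for i, res in enumerate(residues):
            if not CHI_ATOMS[res.aa_type]:
                continue
            if res.coord("N") is None or res.coord("CA") is None \
                    or res.coord("C") is None:
                continue
            active.append(i)
        self.active = active

        cand: dict[int, dict] = {}
        for i in active:
            res = residues[i]
            phi, psi = dihedrals[i]
            rots = library.get(res.aa_type, phi, psi)
            chi_sets = np.array([r.chis for r in rots], dtype=float)
            if chi_sets.ndim == 1:
                chi_sets = chi_sets.reshape(len(rots), -1)
            if rng is not None and params.jitter_sd_scale > 0:
                sds = np.array([r.sds for r in rots], dtype=float).reshape(
                    chi_sets.shape)
                chi_sets = chi_sets + rng.normal(size=chi_sets.shape) * \
                    (params.jitter_sd_scale * sds)
            names, coords = _place_candidates(
                res.aa_type, res.coord("N"), res.coord("CA"), res.coord("C"),
                chi_sets)
            probs = np.array([r.prob for r in rots])
            radii = np.array([VDW_RADII[element_of(nm)] for nm in names])
            beyond = np.array([nm != "CB" for nm in names])
            flat = np.ascontiguousarray(coords[:, beyond, :].reshape(-1, 3))
            flat_r = np.tile(radii[beyond], coords.shape[0])
            center = flat.mean(axis=0) if len(flat) else np.zeros(3)
            reach = (np.sqrt(((flat - center) ** 2).sum(axis=1)).max()
                     if len(flat) else 0.0)
            cand[i] = {
                "names": names, "coords": coords,
                "penalty": -np.log(np.maximum(probs, _MIN_ROT_PROB)),
                "most_probable": int(np.argmax(probs)),
                "flat": flat, "flat_r": flat_r,
                "center": center, "reach": reach,
                "n_cand": coords.shape[0],
            }
        self.cand = cand

        # constant energy terms: membrane mismatch everywhere plus the
        # rotamer term of chi-bearing residues that cannot be repacked
        _, regions = membrane_depth(model, spec)
        static = sum(_hydropathy_mismatch(r.aa_type, reg)
                     for r, reg in zip(residues, regions)) * params.membrane_weight
        from .geometry_eval import compute_chi_angles
        for i, res in enumerate(residues):
            if not CHI_ATOMS[res.aa_type] or i in cand:
                continue
            rec = compute_chi_angles(res)
            if all(c is None for c in rec.chi):
                continue
            rot = library.nearest(res.aa_type, *dihedrals[i], rec.chi)
            static += params.rotamer_weight * -np.log(max(rot.prob, _MIN_ROT_PROB))
        self.static = static

        # canonical atom layout: per residue its static heavy atoms, then
        # (for repackable residues) the candidate side-chain slots
        coords0, owner, radii_arr, names_all = [], [], [], []
        self.static_atoms: dict[int, list] = {}
        self.sc_rows: dict[int, np.ndarray] = {}
        row = 0
        for i, res in enumerate(residues):
            if i in cand:
                topo_names = set(cand[i]["names"])
                keep = [a for a in res.heavy_atoms() if a.name not in topo_names]
            else:
                keep = res.heavy_atoms()
            self.static_atoms[i] = keep
            for a in keep:
                coords0.append(a.coord)
                owner.append(i)
                radii_arr.append(VDW_RADII[a.element])
                names_all.append(a.name)
                row += 1
            if i in cand:
                c = cand[i]
                mp = c["most_probable"]
                rows = []
                for k, nm in enumerate(c["names"]):
                    coords0.append(c["coords"][mp, k])
                    owner.append(i)
                    radii_arr.append(VDW_RADII[element_of(nm)])
                    names_all.append(nm)
                    rows.append(row)
                    row += 1
                self.sc_rows[i] = np.array(rows)
        self.coords0 = np.array(coords0, dtype=float)
        self.owner = np.array(owner)
        self.radii = np.array(radii_arr, dtype=float)
        self.names = names_all
        self.is_sc = np.array([nm not in BACKBONE_ATOMS for nm in names_all])
        self.is_bbcb = np.array([nm in BACKBONE_ATOMS or nm == "CB"
                                 for nm in names_all])
        self.other_idx = {i: np.nonzero(self.owner != i)[0] for i in cand}
        self.current0 = {i: cand[i]["most_probable"] for i in cand}
        self.e_init = self._total(self.coords0, self.current0) + static

    # -- energy machinery ---------------------------------------------------

    def _total(self, coords: np.ndarray, current: dict) -> float:
        p = self.params
        from scipy.spatial import cKDTree
        tree = cKDTree(coords)
        reach = p.clash_scale * 2.0 * self.radii.max()
        pairs = tree.query_pairs(reach, output_type="ndarray")
        steric = 0.0
        if len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            is_bb = ~self.is_sc
            keep = self.owner[i] != self.owner[j]
            keep &= ~(is_bb[i] & is_bb[j])
            adjacent = (self.chain_idx[self.owner[i]] == self.chain_idx[self.owner[j]]) \
                & (np.abs(self.owner[i] - self.owner[j]) == 1)
            keep &= ~(adjacent & self.is_bbcb[i] & self.is_bbcb[j])
            i, j = i[keep], j[keep]
            d = np.linalg.norm(coords[i] - coords[j], axis=1)
            steric = float(_steric_pair_energy(d, self.radii[i] + self.radii[j],
                                               p.clash_scale).sum())
        rot = sum(self.cand[i]["penalty"][current[i]] for i in current)
        return p.steric_weight * steric + p.rotamer_weight * float(rot)

    def _local_energies(self, coords: np.ndarray, i: int) -> np.ndarray:
        c = self.cand[i]
        flat = c["flat"]
        ncand = c["n_cand"]
        scale = self.params.clash_scale
        if not len(flat):
            steric = np.zeros(ncand)
        else:
            other_idx = self.other_idx[i]
            if _HAVE_NUMBA:
                steric = _steric_per_candidate(
                    flat, c["flat_r"], ncand, coords[other_idx],
                    self.radii[other_idx], c["center"], c["reach"], scale)
            else:
                k = len(flat) // ncand
                other = coords[other_idx]
                d2c = ((other - c["center"]) ** 2).sum(axis=1)
                margin = c["reach"] + 2.0 * scale * self.radii.max()
                near = d2c < margin * margin
                other = other[near]
                steric = np.zeros(ncand)
                if len(other):
                    other_r = self.radii[other_idx][near]
                    d2 = ((flat[:, None, :] - other[None, :, :]) ** 2).sum(axis=2)
                    thr = scale * (c["flat_r"][:, None] + other_r[None, :])
                    hit = d2 < thr * thr
                    if hit.any():
                        pen = np.zeros_like(d2)
                        pen[hit] = (thr[hit] - np.sqrt(d2[hit])) ** 2
                        steric = pen.reshape(ncand, k, -1).sum(axis=(1, 2))
        return (self.params.steric_weight * steric
                + self.params.rotamer_weight * c["penalty"])

    def _best_candidate(self, coords: np.ndarray, i: int, cur: int):
        local = self._local_energies(coords, i)
        best = int(np.argmin(local))
        if local[best] >= local[cur] - 1e-12:
            return 0.0, cur
        return float(local[best] - local[cur]), best

    # -- seeded run ---------------------------------------------------------

    def run(self, seed: int, rng: np.random.Generator | None = None) -> RepackResult:
        if rng is None:
            rng = np.random.default_rng(seed)
        coords = self.coords0.copy()
        current = dict(self.current0)
        energy = self.e_init
        trace = [self.e_input, self.e_init]
        active = self.active_repackable()

        if self.params.anneal and self.params.max_sweeps > 1:
            # Metropolis sweeps with a geometric temperature schedule,
            # finished off by greedy quench sweeps below
            temps = np.geomspace(self.params.anneal_t_start,
                                 max(self.params.anneal_t_end, 1e-6),
                                 self.params.max_sweeps - 1)
            for temp in temps:
                for k in rng.permutation(len(active)):
                    i = active[k]
                    c = self.cand[i]
                    proposal = int(rng.integers(c["n_cand"]))
                    if proposal == current[i]:
                        continue
                    local = self._local_energies(coords, i)
                    delta = float(local[proposal] - local[current[i]])
                    if delta <= 0 or rng.random() < np.exp(-delta / temp):
                        energy += delta
                        current[i] = proposal
                        coords[self.sc_rows[i]] = c["coords"][proposal]
                trace.append(energy)

        for _ in range(self.params.max_sweeps):
            changed = False
            for k in rng.permutation(len(active)):
                i = active[k]
                delta, best = self._best_candidate(coords, i, current[i])
                if best != current[i] and delta < -1e-12:
                    energy += delta
                    current[i] = best
                    coords[self.sc_rows[i]] = self.cand[i]["coords"][best]
                    changed = True
            trace.append(energy)
            if not changed:
                break
        return RepackResult(model=self._materialize(current),
                            final_energy=energy, energy_trace=trace, seed=seed)

    def active_repackable(self):
        return [i for i in self.active if i in self.cand]

    def _materialize(self, current: dict) -> StructureModel:
        chains = []
        i = 0
        for chain_id, chain in self.model.chains:
            out_res = []
            for res in chain:
                if i in self.cand:
                    c = self.cand[i]
                    atoms = [Atom(a.name, a.element, a.coord.copy(),
                                  a.occupancy, a.temp_factor, a.is_hydrogen)
                             for a in self.static_atoms[i]]
                    atoms += [a for a in res.atoms
                              if a.is_hydrogen and a.name in ("H", "H1", "H2", "H3")]
                    which = current[i]
                    atoms += [Atom(nm, element_of(nm), c["coords"][which, k].copy())
                              for k, nm in enumerate(c["names"])]
                else:
                    atoms = [Atom(a.name, a.element, a.coord.copy(),
                                  a.occupancy, a.temp_factor, a.is_hydrogen)
                             for a in res.atoms]
                out_res.append(Residue(res.seq_number, res.insertion_code,
                                       res.aa_type, atoms))
                i += 1
            chains.append((chain_id, out_res))
        return StructureModel(self.model.target_id, self.model.model_id, chains)


def repack(model: StructureModel, library: RotamerLibrary | None = None,
           params: PackingParams | None = None,
           spec: MembraneSpec | None = None, seed: int = 0) -> RepackResult:
    """Greedy fixed-backbone repack.

    Every chi-bearing residue with a complete backbone is initialized at its
    most probable rotamer for its (phi, psi) bin, then residues are swept in
    seeded random order, greedily accepting the lowest-energy rotamer
    (current conformation included as a candidate) until a sweep changes
    nothing or ``max_sweeps`` is reached.  GLY and ALA are skipped; backbone
    atoms are bit-identical to the input.
    """
    if library is None:
        library = _default_library()
    if params is None:
        params = PackingParams()
    if spec is None:
        spec = MembraneSpec()
    rng = np.random.default_rng(seed)
    ctx = _RepackContext(model, library, params, spec,
                         rng if params.jitter_sd_scale > 0 else None)
    return ctx.run(seed, rng)


def generate_decoys(model: StructureModel, n: int = 10, base_seed: int = 0,
                    library: RotamerLibrary | None = None,
                    params: PackingParams | None = None,
                    spec: MembraneSpec | None = None):
    """Generate ``n`` repacked decoys; decoy i uses seed ``base_seed + i``.

    All decoys share the input backbone exactly; the set is deterministic
    given ``base_seed`` and equals ``[repack(model, seed=base_seed + i)]``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params is None:
        params = PackingParams()
    if params.jitter_sd_scale > 0:
        return [repack(model, library, params, spec, seed=base_seed + i)
                for i in range(1, n + 1)]
    if library is None:
        library = _default_library()
    if spec is None:
        spec = MembraneSpec()
    ctx = _RepackContext(model, library, params, spec)
    return [ctx.run(base_seed + i) for i in range(1, n + 1)]
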