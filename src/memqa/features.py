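"""Per-residue structural and sequence features for quality prediction.

Structural features are computed from the model itself: solvent accessible
surface area (Shrake-Rupley sphere sampling), three-state secondary
structure from backbone hydrogen bonds (Kabsch-Sander electrostatic energy),
atom-atom contact counts in a 13-class atom typing, residue-residue contact
counts by partner amino acid, and depth in an implicit membrane slab.
Sequence features (PSSM, predicted secondary structure, burial and membrane
topology) are carried by a :class:`SequenceProfile`, read from a plain-text
profile file or produced by the synthetic generator.  Both sets are merged
into a windowed per-residue :class:`FeatureMatrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._chem import AA_ONE, HYDROPATHY, MAX_ASA, VDW_RADII, atom_class, ATOM_CLASSES
from .model_io import StructureModel

logger = logging.getLogger(__name__)

TOPOLOGY_LABELS = ("membrane", "inside", "outside")
REGION_LABELS = ("core", "interface", "water")

__all__ = [
    "MembraneSpec",
    "SequenceProfile",
    "FeatureMatrix",
    "SASAResult",
    "shrake_rupley_sasa",
    "assign_secondary_structure",
    "atom_contact_counts",
    "residue_contact_counts",
    "membrane_depth",
    "read_profile",
    "write_profile",
    "build_feature_matrix",
    "base_feature_names",
]


@dataclass
class MembraneSpec:
    """Implicit membrane slab: a flat bilayer normal to ``normal_axis``.

    Models are assumed pre-oriented with the membrane normal along z and the
    bilayer centre at z = 0; ``half_thickness`` is half the hydrophobic core
    width in Angstrom.
    """

    normal_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    center: float = 0.0
    half_thickness: float = 15.0
    interface_width: float = 6.0

    def __post_init__(self) -> None:
        self.normal_axis = np.asarray(self.normal_axis, dtype=float)
        n = np.linalg.norm(self.normal_axis)
        if n == 0 or self.half_thickness <= 0:
            raise ValueError("membrane normal must be nonzero and half_thickness > 0")
        self.normal_axis = self.normal_axis / n


@dataclass
class SequenceProfile:
    """Sequence-derived per-residue features (computed once per target)."""

    sequence: str
    pssm: np.ndarray          # (L, 20) log-odds, columns in AA_ONE order
    pred_ss: np.ndarray       # (L, 3) probabilities (H, E, C)
    pred_burial: np.ndarray   # (L,) in [0, 1]
    pred_topology: list       # (L,) labels in TOPOLOGY_LABELS

    def __post_init__(self) -> None:
        L = len(self.sequence)
        self.pssm = np.asarray(self.pssm, dtype=float)
        self.pred_ss = np.asarray(self.pred_ss, dtype=float)
        self.pred_burial = np.asarray(self.pred_burial, dtype=float)
        if self.pssm.shape != (L, 20) or self.pred_ss.shape != (L, 3) \
                or self.pred_burial.shape != (L,) or len(self.pred_topology) != L:
            raise ValueError("profile arrays must all have the sequence length")
        if np.any(np.abs(self.pred_ss.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("pred_ss rows must lie on the probability simplex")
        if any(t not in TOPOLOGY_LABELS for t in self.pred_topology):
            raise ValueError("invalid topology label")


@dataclass
class FeatureMatrix:
    values: np.ndarray        # (n_residues, n_columns), raw (unnormalized)
    columns: list             # ordered column names (the feature spec)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column count mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")


@dataclass
class SASAResult:
    atom_sasa: np.ndarray      # per heavy atom, model.heavy_coords() order
    residue_sasa: np.ndarray   # per residue
    relative: np.ndarray       # residue SASA / Gly-X-Gly maximum, clipped to [0, 1]


# ---------------------------------------------------------------------------
# solvent accessible surface area

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


try:
    from numba import njit as _njit

    @_njit(cache=False, fastmath=False)
    def _sasa_accessible_fraction(coords, inflated, nbr_idx, nbr_ptr, pts):
        n = coords.shape[0]
        npts = pts.shape[0]
        out = np.empty(n)
        for i in range(n):
            r = inflated[i]
            acc = 0
            last = -1  # consecutive spiral points are often buried by the
            # same neighbour, so test the previous blocker first
            for p in range(npts):
                px = coords[i, 0] + r * pts[p, 0]
                py = coords[i, 1] + r * pts[p, 1]
                pz = coords[i, 2] + r * pts[p, 2]
                free = True
                if last >= 0:
                    dx = px - coords[last, 0]
                    dy = py - coords[last, 1]
                    dz = pz - coords[last, 2]
                    if dx * dx + dy * dy + dz * dz <= inflated[last] * inflated[last]:
                        free = False
                if free:
                    for t in range(nbr_ptr[i], nbr_ptr[i + 1]):
                        j = nbr_idx[t]
                        if j == last:
                            continue
                        dx = px - coords[j, 0]
                        dy = py - coords[j, 1]
                        dz = pz - coords[j, 2]
                        if dx * dx + dy * dy + dz * dz <= inflated[j] * inflated[j]:
                            free = False
                            last = j
                            break
                if free:
                    acc += 1
            out[i] = acc / npts
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False


def shrake_rupley_sasa(model: StructureModel, probe: float = 1.4,
                       n_points: int = 960) -> SASAResult:
    """Shrake-Rupley solvent accessible surface area (heavy atoms only).

    Each atom's sphere (radius r + probe) is sampled at ``n_points`` points;
    a point is accessible when outside every neighbour's inflated sphere.
    """
    coords, owners = model.heavy_coords()
    n_atoms = len(owners)
    radii = np.empty(n_atoms)
    res_of = np.empty(n_atoms, dtype=int)
    for k, (ri, atom) in enumerate(owners):
        try:
            radii[k] = VDW_RADII[atom.element]
        except KeyError:
            raise ValueError(
                f"no van der Waals radius for element {atom.element!r} "
                f"(atom {atom.name} in residue index {ri})") from None
        res_of[k] = ri
    pts = _sphere_points(n_points)
    inflated = radii + probe
    tree = cKDTree(coords)
    # CSR neighbour lists, nearest first (helps the early-exit point test)
    pairs = tree.query_pairs(2.0 * inflated.max(), output_type="ndarray")
    if len(pairs):
        both = np.vstack([pairs, pairs[:, ::-1]])
        d2 = ((coords[both[:, 0]] - coords[both[:, 1]]) ** 2).sum(axis=1)
        order = np.lexsort((d2, both[:, 0]))
        both = both[order]
        nbr_idx = both[:, 1].astype(np.int64)
        counts = np.bincount(both[:, 0], minlength=n_atoms)
    else:
        nbr_idx = np.zeros(0, dtype=np.int64)
        counts = np.zeros(n_atoms, dtype=np.int64)
    nbr_ptr = np.zeros(n_atoms + 1, dtype=np.int64)
    np.cumsum(counts, out=nbr_ptr[1:])

    if _HAVE_NUMBA:
        frac = _sasa_accessible_fraction(coords, inflated, nbr_idx, nbr_ptr, pts)
    else:
        frac = np.empty(n_atoms)
        for k in range(n_atoms):
            nb = nbr_idx[nbr_ptr[k]:nbr_ptr[k + 1]]
            sample = coords[k] + inflated[k] * pts
            if len(nb):
                d2 = ((sample[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
                frac[k] = np.all(d2 > (inflated[nb] ** 2)[None, :], axis=1).mean()
            else:
                frac[k] = 1.0
    atom_sasa = frac * 4.0 * np.pi * inflated ** 2
    n_res = model.n_residues()
    residue_sasa = np.zeros(n_res)
    np.add.at(residue_sasa, res_of, atom_sasa)
    max_asa = np.array([MAX_ASA[r.aa_type] for r in model.residues()])
    relative = np.clip(residue_sasa / max_asa, 0.0, 1.0)
    return SASAResult(atom_sasa, residue_sasa, relative)


# ---------------------------------------------------------------------------
# secondary structure

_HB_FACTOR = 0.084 * 332.0  # kcal/mol, Kabsch-Sander electrostatic model
_HB_CUTOFF = -0.5


def assign_secondary_structure(model: StructureModel) -> list:
    """Three-state secondary structure (H/E/C) from backbone hydrogen bonds.

    Amide hydrogens are reconstructed geometrically; an H-bond exists when
    the Kabsch-Sander electrostatic energy is below -0.5 kcal/mol.  H marks
    residues inside two consecutive i -> i+4 bonded turns, E marks bridge
    (ladder) partners, everything else is C.  Residues with incomplete
    backbones are labelled C.
    """
    residues = model.residues()
    chain_idx = np.asarray(model.chain_index())
    n = len(residues)
    N = np.full((n, 3), np.nan)
    CA = np.full((n, 3), np.nan)
    C = np.full((n, 3), np.nan)
    O = np.full((n, 3), np.nan)
    ok = np.zeros(n, dtype=bool)
    for i, res in enumerate(residues):
        cN, cCA, cC, cO = (res.coord(a) for a in ("N", "CA", "C", "O"))
        if cN is None or cCA is None or cC is None or cO is None:
            continue
        N[i], CA[i], C[i], O[i] = cN, cCA, cC, cO
        ok[i] = True
    # reconstruct amide H: on N, opposite the preceding carbonyl oxygen
    H = np.full((n, 3), np.nan)
    has_h = np.zeros(n, dtype=bool)
    for i in range(1, n):
        if ok[i] and ok[i - 1] and chain_idx[i] == chain_idx[i - 1]:
            v = C[i - 1] - O[i - 1]
            H[i] = N[i] + v / np.linalg.norm(v)
            has_h[i] = True

    # hbond[d, a]: N-H of residue d donates to C=O of residue a
    donors = np.nonzero(has_h)[0]
    acceptors = np.nonzero(ok)[0]
    hbond = np.zeros((n, n), dtype=bool)
    if len(donors) and len(acceptors):
        # CA-CA prefilter: 9 A is generous for an H-bond
        dtree = cKDTree(CA[donors])
        atree = cKDTree(CA[acceptors])
        close = dtree.query_ball_tree(atree, 9.0)
        dd = np.array([d for k, d in enumerate(donors) for _ in close[k]],
                      dtype=int)
        aa = np.array([acceptors[ja] for k in range(len(donors))
                       for ja in close[k]], dtype=int)
        if len(dd):
            keep = ~((np.abs(dd - aa) < 2) & (chain_idx[dd] == chain_idx[aa]))
            dd, aa = dd[keep], aa[keep]
            r_on = np.linalg.norm(O[aa] - N[dd], axis=1)
            r_ch = np.linalg.norm(C[aa] - H[dd], axis=1)
            r_oh = np.linalg.norm(O[aa] - H[dd], axis=1)
            r_cn = np.linalg.norm(C[aa] - N[dd], axis=1)
            rmin = np.minimum(np.minimum(r_on, r_ch), np.minimum(r_oh, r_cn))
            with np.errstate(divide="ignore"):
                e = _HB_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            good = (rmin >= 0.5) & (e < _HB_CUTOFF)
            hbond[dd[good], aa[good]] = True

    labels = np.array(["C"] * n, dtype=object)
    same_next = np.zeros(n, dtype=bool)  # same chain as the next residue
    same_next[:-1] = chain_idx[:-1] == chain_idx[1:]

    # helix: two consecutive i -> i+4 turns mark i+1 .. i+4
    if n >= 6:
        run_ok = np.all([same_next[k:k + n - 5] for k in range(5)], axis=0)
        starts = np.nonzero(run_ok
                            & hbond[np.arange(4, n - 1), np.arange(n - 5)]
                            & hbond[np.arange(5, n), np.arange(1, n - 4)])[0]
        for i in starts:
            labels[i + 1:i + 5] = "H"

    # bridges (parallel / antiparallel) mark both partners E
    def shifted(di, dj):
        """matrix M[i, j] = hbond[i + di, j + dj] (False outside)."""
        out = np.zeros((n, n), dtype=bool)
        si = slice(max(0, -di), min(n, n - di))
        sj = slice(max(0, -dj), min(n, n - dj))
        out[si, sj] = hbond[max(0, di):min(n, n + di),
                            max(0, dj):min(n, n + dj)]
        return out

    prev_ok = np.zeros(n, dtype=bool)  # same chain as the previous residue
    prev_ok[1:] = chain_idx[1:] == chain_idx[:-1]
    next_ok = same_next
    pn_i = prev_ok[:, None] & next_ok[:, None]
    pn_j = prev_ok[None, :] & next_ok[None, :]
    anti = (hbond & hbond.T) | (shifted(-1, 1) & shifted(-1, 1).T & pn_i & pn_j)
    par = (shifted(-1, 0) & shifted(0, 1).T & pn_i) | \
        (shifted(0, 1) & shifted(-1, 0).T & pn_j)
    bridge = anti | par
    ii, jj = np.nonzero(bridge)
    sep_ok = np.abs(ii - jj) > 2
    in_bridge = np.zeros(n, dtype=bool)
    in_bridge[ii[sep_ok]] = True
    in_bridge[jj[sep_ok]] = True
    labels[in_bridge & (labels != "H")] = "E"
    labels[~ok] = "C"  # incomplete backbone is never H or E
    return list(labels)


# ---------------------------------------------------------------------------
# contacts

def atom_contact_counts(model: StructureModel, cutoff: float = 4.5) -> np.ndarray:
    """Per-residue counts of contacting heavy atoms by 13-class atom type.

    An other-residue heavy atom is counted (once) when it lies within
    ``cutoff`` (half-open, d < cutoff) of any atom of the residue; contacts
    with sequence neighbours (same chain, position difference <= 1) are
    excluded.
    """
    coords, owners = model.heavy_coords()
    chain_idx = model.chain_index()
    residues = model.residues()
    res_of = np.array([ri for ri, _ in owners])
    classes = np.array([ATOM_CLASSES.index(atom_class(residues[ri].aa_type, a.name))
                        for ri, a in owners])
    n_res = model.n_residues()
    counts = np.zeros((n_res, len(ATOM_CLASSES)), dtype=float)
    if len(coords) == 0:
        return counts
    chain_idx = np.asarray(chain_idx)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if not len(pairs):
        return counts
    a, b = pairs[:, 0], pairs[:, 1]
    ri, rj = res_of[a], res_of[b]
    keep = ri != rj
    keep &= ~((chain_idx[ri] == chain_idx[rj]) & (np.abs(ri - rj) <= 1))
    keep &= ((coords[a] - coords[b]) ** 2).sum(axis=1) < cutoff * cutoff
    a, b, ri, rj = a[keep], b[keep], ri[keep], rj[keep]
    n_atoms = len(coords)
    # each partner atom counted once per residue, even if near several atoms
    keys = np.unique(np.concatenate([ri.astype(np.int64) * n_atoms + b,
                                     rj.astype(np.int64) * n_atoms + a]))
    np.add.at(counts, (keys // n_atoms, classes[keys % n_atoms]), 1.0)
    return counts


def residue_contact_counts(model: StructureModel, cutoff: float = 8.0) -> np.ndarray:
    """Per-residue counts of CB-CB contacts binned by partner amino acid.

    GLY uses CA.  A contact is a CB-CB distance below ``cutoff`` with
    sequence separation above 1 (different chains always qualify).
    """
    residues = model.residues()
    chain_idx = model.chain_index()
    n = len(residues)
    cb = np.full((n, 3), np.nan)
    for i, res in enumerate(residues):
        c = res.coord("CA") if res.aa_type == "GLY" else res.coord("CB")
        if c is None:
            c = res.coord("CA")
        if c is not None:
            cb[i] = c
    aa_idx = np.array([AA_ONE.index(r.one_letter) for r in residues])
    counts = np.zeros((n, 20), dtype=float)
    valid = ~np.isnan(cb[:, 0])
    idx = np.nonzero(valid)[0]
    if len(idx) < 2:
        return counts
    tree = cKDTree(cb[idx])
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    for a, b in pairs:
        i, j = idx[a], idx[b]
        if chain_idx[i] == chain_idx[j] and abs(i - j) <= 1:
            continue
        if np.linalg.norm(cb[i] - cb[j]) >= cutoff:
            continue
        counts[i, aa_idx[j]] += 1
        counts[j, aa_idx[i]] += 1
    return counts


# ---------------------------------------------------------------------------
# membrane depth

def membrane_depth(model: StructureModel, spec: MembraneSpec | None = None):
    """Per-residue unsigned depth from the bilayer centre and region label."""
    if spec is None:
        spec = MembraneSpec()
    depths = []
    labels = []
    for res in model.residues():
        ca = res.coord("CA")
        if ca is None:
            ca = res.heavy_atoms()[0].coord if res.heavy_atoms() else np.zeros(3)
        depth = abs(float(np.dot(ca, spec.normal_axis)) - spec.center)
        depths.append(depth)
        if depth < spec.half_thickness:
            labels.append("core")
        elif depth < spec.half_thickness + spec.interface_width:
            labels.append("interface")
        else:
            labels.append("water")
    return np.array(depths), labels


# ---------------------------------------------------------------------------
# profile I/O

PROFILE_HEADER = "# MEMQA-PROFILE v1"


def write_profile(profile: SequenceProfile, path) -> None:
    cols = ["index", "aa"] + [f"pssm_{a}" for a in AA_ONE] + \
        ["pH", "pE", "pC", "burial", "topology"]
    with open(path, "w") as fh:
        fh.write(PROFILE_HEADER + "\n")
        fh.write("\t".join(cols) + "\n")
        for i, aa in enumerate(profile.sequence):
            row = [str(i + 1), aa]
            row += [f"{v:.4f}" for v in profile.pssm[i]]
            row += [f"{v:.6f}" for v in profile.pred_ss[i]]
            row += [f"{profile.pred_burial[i]:.4f}", profile.pred_topology[i]]
            fh.write("\t".join(row) + "\n")


def read_profile(path, expected_sequence: str) -> SequenceProfile:
    """Read a ``MEMQA-PROFILE v1`` file, validating against the sequence."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0].strip() != PROFILE_HEADER:
        raise ValueError(f"{path}: missing {PROFILE_HEADER!r} header")
    rows = [ln for ln in lines[1:] if ln and not ln.startswith("#")
            and not ln.startswith("index\t")]
    if len(rows) != len(expected_sequence):
        raise ValueError(
            f"{path}: profile has {len(rows)} rows but sequence has "
            f"{len(expected_sequence)} residues")
    L = len(rows)
    pssm = np.zeros((L, 20))
    ss = np.zeros((L, 3))
    burial = np.zeros(L)
    topo = []
    for i, row in enumerate(rows):
        parts = row.split("\t")
        if len(parts) != 27:
            raise ValueError(f"{path}: malformed row {i + 1}: expected 27 fields")
        aa = parts[1]
        if aa != expected_sequence[i]:
            raise ValueError(
                f"{path}: residue {i + 1} is {aa!r} but sequence has "
                f"{expected_sequence[i]!r}")
        pssm[i] = [float(v) for v in parts[2:22]]
        ss[i] = [float(v) for v in parts[22:25]]
        burial[i] = float(parts[25])
        topo.append(parts[26])
        s = ss[i].sum()
        if s <= 0:
            raise ValueError(f"{path}: non-positive pred_ss row {i + 1}")
        if abs(s - 1.0) > 1e-6:
            if abs(s - 1.0) > 1e-3:
                logger.warning("%s: pred_ss row %d sums to %.4f, renormalizing",
                               path, i + 1, s)
            ss[i] /= s
    return SequenceProfile(expected_sequence, pssm, ss,
                           np.clip(burial, 0.0, 1.0), topo)


# ---------------------------------------------------------------------------
# feature matrix

_SS_STATES = ("H", "E", "C")


def base_feature_names() -> list:
    names = [f"pssm_{a}" for a in AA_ONE]
    names += ["pred_H", "pred_E", "pred_C", "pred_burial"]
    names += [f"obs_{s}" for s in _SS_STATES]
    names += ["rel_sasa", "mem_depth"]
    names += [f"region_{r}" for r in REGION_LABELS]
    names += [f"ac_{c}" for c in ATOM_CLASSES]
    names += [f"rc_{a}" for a in AA_ONE]
    return names


def build_feature_matrix(model: StructureModel, profile: SequenceProfile,
                         spec: MembraneSpec | None = None, window: int = 9,
                         sasa_points: int = 960,
                         precomputed: dict | None = None) -> FeatureMatrix:
    """Combine structural and sequence features into a windowed matrix.

    Each residue's row concatenates, over a symmetric sequence window, the
    base per-residue features; positions outside the chain are zero-padded
    and marked by a per-offset terminus indicator column.  ``precomputed``
    may supply backbone-only features (``obs_ss``, ``res_contacts``,
    ``depth_region``) that are identical across side-chain decoys of one
    backbone.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if spec is None:
        spec = MembraneSpec()
    n = model.n_residues()
    seq = "".join(r.one_letter for r in model.residues())
    if len(profile.sequence) != n or profile.sequence != seq:
        raise ValueError("profile does not match the model sequence")
    pre = precomputed or {}

    obs_ss = pre.get("obs_ss")
    if obs_ss is None:
        obs_ss = assign_secondary_structure(model)
    depth_region = pre.get("depth_region")
    if depth_region is None:
        depth_region = membrane_depth(model, spec)
    depths, regions = depth_region
    res_contacts = pre.get("res_contacts")
    if res_contacts is None:
        res_contacts = residue_contact_counts(model)
    sasa = shrake_rupley_sasa(model, n_points=sasa_points)
    atom_contacts = atom_contact_counts(model)

    base = np.zeros((n, len(base_feature_names())))
    col = 0
    base[:, col:col + 20] = profile.pssm; col += 20
    base[:, col:col + 3] = profile.pred_ss; col += 3
    base[:, col] = profile.pred_burial; col += 1
    for s in _SS_STATES:
        base[:, col] = [1.0 if lab == s else 0.0 for lab in obs_ss]; col += 1
    base[:, col] = sasa.relative; col += 1
    base[:, col] = depths; col += 1
    for r in REGION_LABELS:
        base[:, col] = [1.0 if lab == r else 0.0 for lab in regions]; col += 1
    base[:, col:col + 13] = atom_contacts; col += 13
    base[:, col:col + 20] = res_contacts; col += 20

    names = base_feature_names()
    half = window // 2
    chain_idx = np.asarray(model.chain_index())
    width = len(names) + 1  # + terminus indicator
    values = np.zeros((n, window * width))
    columns = []
    idx = np.arange(n)
    for w, off in enumerate(range(-half, half + 1)):
        columns += [f"{nm}@{off:+d}" for nm in names] + [f"pad@{off:+d}"]
        lo = w * width
        j = idx + off
        valid = (j >= 0) & (j < n)
        valid[valid] &= chain_idx[j[valid]] == chain_idx[idx[valid]]
        values[valid, lo:lo + len(names)] = base[j[valid]]
        values[~valid, lo + len(names)] = 1.0
    return FeatureMatrix(values, columns)


def hydropathy_of(aa_type: str) -> float:
    return HYDROPATHY[aa_type]
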