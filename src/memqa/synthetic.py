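"""Synthetic membrane-protein fixtures: helix bundles, graded decoys, profiles.

The generator produces alpha-helical bundles oriented along the membrane
normal, decoy sets of controlled backbone quality (smooth correlated
backbone perturbations of chosen magnitude), degraded side-chain packings
(uniformly re-drawn chi angles for a chosen fraction of residues) and noisy
sequence profiles consistent with the native.  Decoy realism is secondary
to controllable gradation: selection benchmarks need a known quality
spread, not folding physics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ._chem import CHI_ATOMS, ONE_TO_THREE
from .features import MembraneSpec, SequenceProfile, membrane_depth, \
    assign_secondary_structure, shrake_rupley_sasa
from .geometry_eval import place_atom, tm_score
from .model_io import Atom, Residue, StructureModel, validate_model
from .repack import backbone_dihedrals, builtin_library, place_side_chain
from ._chem import (ANG_CA_C_N, ANG_CA_C_O, ANG_C_N_CA, ANG_N_CA_C,
                    BB_CA_C, BB_C_N, BB_C_O, BB_N_CA)

__all__ = [
    "SyntheticTarget",
    "make_helix_bundle",
    "perturb_backbone",
    "randomize_side_chains",
    "make_profile",
    "make_benchmark",
]

_HELIX_PHI = -57.0
_HELIX_PSI = -47.0

_HYDROPHOBIC = "LIVFAM"
_POLAR = "STNQKREDYWH"
_LOOP_AA = "GSNDT"


@dataclass
class SyntheticTarget:
    target_id: str
    native: StructureModel
    models: dict           # model id -> StructureModel
    true_tm: dict          # model id -> TM-score vs native
    profile: SequenceProfile
    provenance: dict


# ---------------------------------------------------------------------------
# backbone construction helpers

def _ideal_helix_backbone(n_res: int):
    """N/CA/C/O coordinates of an ideal alpha helix built by internal
    coordinates, aligned with its axis along +z and centred at the origin."""
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))
    # seed the first three atoms in an arbitrary frame
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BB_N_CA, 0.0, 0.0)
    ang = np.radians(ANG_N_CA_C)
    C[0] = CA[0] + (BB_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0]))
    for i in range(n_res):
        if i > 0:
            N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                              BB_C_N, ANG_CA_C_N, _HELIX_PSI)
            CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                               BB_N_CA, ANG_C_N_CA, 180.0)  # omega
            C[i] = place_atom(C[i - 1], N[i], CA[i],
                              BB_CA_C, ANG_N_CA_C, _HELIX_PHI)
        if i + 1 < n_res:
            n_next = place_atom(N[i], CA[i], C[i], BB_C_N, ANG_CA_C_N, _HELIX_PSI)
        else:
            n_next = place_atom(N[i], CA[i], C[i], BB_C_N, ANG_CA_C_N, _HELIX_PSI)
        O[i] = place_atom(n_next, CA[i], C[i], BB_C_O, ANG_CA_C_O, 180.0)
    # align principal axis with +z (chain running towards +z), centre at origin
    centroid = CA.mean(axis=0)
    X = CA - centroid
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    axis = Vt[0]
    if np.dot(CA[-1] - CA[0], axis) < 0:
        axis = -axis
    R = _rotation_between(axis, np.array([0.0, 0.0, 1.0]))
    return tuple((arr - centroid) @ R.T for arr in (N, CA, C, O))


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180-degree flip about any axis perpendicular to a
        p = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, p)
        v /= np.linalg.norm(v)
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _hermite(p0, p1, t0, t1, s):
    h00 = 2 * s ** 3 - 3 * s ** 2 + 1
    h10 = s ** 3 - 2 * s ** 2 + s
    h01 = -2 * s ** 3 + 3 * s ** 2
    h11 = s ** 3 - s ** 2
    return h00 * p0 + h10 * t0 + h01 * p1 + h11 * t1


def _solve_peptide_link(ca_i, ca_j, up, c_fixed=None, n_fixed=None):
    """Place C(i) and N(j) between consecutive CA atoms by iterative
    distance-constraint projection (CA-C 1.52, C-N 1.33, N-CA 1.46)."""
    v = ca_j - ca_i
    c = ca_i + 0.38 * v + 0.6 * up if c_fixed is None else c_fixed
    n = ca_j - 0.36 * v + 0.6 * up if n_fixed is None else n_fixed
    for _ in range(40):
        if c_fixed is None:
            d = c - ca_i
            c = ca_i + d * (BB_CA_C / max(np.linalg.norm(d), 1e-9))
        d = n - c
        ln = max(np.linalg.norm(d), 1e-9)
        corr = (ln - BB_C_N) / ln
        if c_fixed is None and n_fixed is None:
            c = c + 0.5 * corr * d
            n = n - 0.5 * corr * d
        elif c_fixed is None:
            c = c + corr * d
        else:
            n = n - corr * d
        if n_fixed is None:
            d = n - ca_j
            n = ca_j + d * (BB_N_CA / max(np.linalg.norm(d), 1e-9))
    return c, n


def make_helix_bundle(n_helices: int, helix_len: int, sequence: str = "auto",
                      seed: int = 0, loop_len: int = 3,
                      target_id: str = "synthetic") -> StructureModel:
    """Ideal alpha-helical bundle with full side chains, membrane-oriented.

    Helices (phi = -57, psi = -47) are placed on a circle whose radius
    scales with ``n_helices``, alternating up/down, connected by short
    smooth loops; side chains are placed at the most probable rotamer.
    With ``sequence="auto"`` the membrane-spanning stretches are
    hydrophobic-biased and the loops polar.  Deterministic per seed.
    """
    if n_helices < 1:
        raise ValueError("n_helices must be >= 1")
    if helix_len < 8:
        raise ValueError("helix_len must be >= 8")
    rng = np.random.default_rng(seed)
    n_loops = n_helices - 1
    total = n_helices * helix_len + n_loops * loop_len

    is_loop = []
    for h in range(n_helices):
        is_loop += [False] * helix_len
        if h < n_loops:
            is_loop += [True] * loop_len

    if sequence == "auto":
        seq_chars = []
        for flag in is_loop:
            pool = _LOOP_AA if flag else \
                (_HYDROPHOBIC if rng.random() < 0.75 else _POLAR)
            seq_chars.append(pool[rng.integers(len(pool))])
        sequence = "".join(seq_chars)
    if len(sequence) != total:
        raise ValueError(f"sequence length {len(sequence)} != {total} residues")

    # rigid helix placement on a circle, alternating up/down
    hN, hCA, hC, hO = _ideal_helix_backbone(helix_len)
    radius = 0.0 if n_helices == 1 else max(5.2, 10.0 / (2.0 * np.sin(np.pi / n_helices)))
    placed = []  # per helix: dict of N/CA/C/O arrays
    flip = _rotation_between(np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0]))
    for h in range(n_helices):
        theta = 2.0 * np.pi * h / max(n_helices, 2)
        offset = np.array([radius * np.cos(theta), radius * np.sin(theta), 0.0])
        spin = _rot_z(np.degrees(theta) + 60.0)
        arrs = {}
        for key, arr in (("N", hN), ("CA", hCA), ("C", hC), ("O", hO)):
            out = arr @ spin.T
            if h % 2 == 1:
                out = out @ flip.T
            arrs[key] = out + offset
        placed.append(arrs)

    # assemble global backbone arrays
    N = np.zeros((total, 3))
    CA = np.zeros((total, 3))
    C = np.zeros((total, 3))
    O = np.full((total, 3), np.nan)
    kinds = np.array(is_loop)
    pos = 0
    bounds = []
    for h in range(n_helices):
        sl = slice(pos, pos + helix_len)
        for key, arr in placed[h].items():
            {"N": N, "CA": CA, "C": C, "O": O}[key][sl] = arr
        bounds.append(sl)
        pos += helix_len + (loop_len if h < n_loops else 0)

    # loops: Hermite path between helix ends, then peptide-link placement
    for h in range(n_loops):
        end = bounds[h].stop - 1
        start = bounds[h + 1].start
        p0, p1 = CA[end], CA[start]
        t0 = placed[h]["CA"][-1] - placed[h]["CA"][-4]
        t1 = placed[h + 1]["CA"][3] - placed[h + 1]["CA"][0]
        chord = np.linalg.norm(p1 - p0)
        t0 = t0 / np.linalg.norm(t0) * chord
        t1 = t1 / np.linalg.norm(t1) * chord
        loop_idx = list(range(end + 1, start))
        for k, i in enumerate(loop_idx, start=1):
            s = k / (loop_len + 1)
            CA[i] = _hermite(p0, p1, t0, t1, s)
        # place C/N/O through the loop junctions; if a residue's N-CA-C
        # frame degenerates to a line, nudge its CA and re-solve once
        path = [end] + loop_idx + [start]
        for attempt in range(4):
            for a, b in zip(path, path[1:]):
                up = _perp_up(CA[b] - CA[a])
                c_fixed = C[a] if a == end else None
                n_fixed = N[b] if b == start else None
                c_new, n_new = _solve_peptide_link(CA[a], CA[b], up,
                                                   c_fixed, n_fixed)
                if a != end:
                    C[a] = c_new
                if b != start:
                    N[b] = n_new
            bad = [i for i in loop_idx if _frame_degenerate(N[i], CA[i], C[i])]
            if not bad:
                break
            for i in bad:
                CA[i] = CA[i] + 0.35 * _perp_up(CA[i + 1] - CA[i - 1]) \
                    + np.array([0.05, 0.0, 0.05]) * (attempt + 1)
        for a, b in zip(path, path[1:]):
            if a == end:
                continue
            d = 2.0 * C[a] - CA[a] - N[b]
            O[a] = C[a] + BB_C_O * d / max(np.linalg.norm(d), 1e-9)

    # build residues
    residues = []
    for i in range(total):
        aa3 = ONE_TO_THREE[sequence[i]]
        atoms = [Atom("N", "N", N[i]), Atom("CA", "C", CA[i]),
                 Atom("C", "C", C[i]), Atom("O", "O", O[i])]
        residues.append(Residue(i + 1, " ", aa3, atoms))
    model = StructureModel(target_id, target_id, [("A", residues)])

    # clash check on CA positions (non-adjacent residues)
    d2 = ((CA[:, None, :] - CA[None, :, :]) ** 2).sum(axis=2)
    ii, jj = np.triu_indices(total, k=2)
    if np.any(d2[ii, jj] < 3.2 ** 2):
        raise ValueError("helix bundle has unresolvable backbone overlap; "
                         "increase radius or reduce helix count")

    # side chains at the most probable rotamer
    lib = builtin_library()
    dihedrals = backbone_dihedrals(model)
    for res, (phi, psi) in zip(model.residues(), dihedrals):
        n_chi = len(CHI_ATOMS[res.aa_type])
        chis = lib.most_probable(res.aa_type, phi, psi).chis[:n_chi] if n_chi \
            else ()
        if res.aa_type == "GLY":
            continue
        side = place_side_chain(res.aa_type,
                                {"N": res.coord("N"), "CA": res.coord("CA"),
                                 "C": res.coord("C")}, chis)
        for name, coord in side.items():
            res.atoms.append(Atom(name, name[0], coord))
    return model


def _frame_degenerate(n, ca, c, min_sin: float = 0.08) -> bool:
    """True when N-CA-C are nearly collinear (no usable side-chain frame)."""
    v1 = n - ca
    v2 = c - ca
    cr = np.cross(v1, v2)
    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
    return denom < 1e-9 or np.linalg.norm(cr) / denom < min_sin


def _rot_z(deg: float) -> np.ndarray:
    r = np.radians(deg)
    return np.array([[np.cos(r), -np.sin(r), 0.0],
                     [np.sin(r), np.cos(r), 0.0],
                     [0.0, 0.0, 1.0]])


def _perp_up(v: np.ndarray) -> np.ndarray:
    z = np.array([0.0, 0.0, 1.0])
    p = z - v * np.dot(z, v) / max(np.dot(v, v), 1e-9)
    n = np.linalg.norm(p)
    if n < 1e-6:
        p = np.array([1.0, 0.0, 0.0])
        n = 1.0
    return p / n


# ---------------------------------------------------------------------------
# decoy generation

def perturb_backbone(native: StructureModel, magnitude: float,
                     seed: int = 0) -> StructureModel:
    """Smooth correlated backbone perturbation of roughly the given RMS (A).

    A Gaussian-smoothed random displacement field (one displacement per
    residue, applied rigidly to the whole residue so internal geometry and
    chi angles are preserved) is scaled to RMS ``magnitude``; stretched
    peptide bonds are clamped back into [1.2, 1.8] A.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    decoy = native.copy()
    if magnitude == 0:
        return decoy
    rng = np.random.default_rng(seed)
    n = decoy.n_residues()
    field = gaussian_filter1d(rng.normal(size=(n, 3)), sigma=5.0, axis=0,
                              mode="nearest")
    field -= field.mean(axis=0)
    rms = np.sqrt((field ** 2).sum(axis=1).mean())
    field *= magnitude / max(rms, 1e-12)
    for disp, res in zip(field, decoy.residues()):
        for atom in res.atoms:
            atom.coord = atom.coord + disp
    # clamp peptide C-N bonds
    for _, chain in decoy.chains:
        for prev, nxt in zip(chain, chain[1:]):
            c = prev.coord("C")
            natom = nxt.atom("N")
            if c is None or natom is None:
                continue
            v = natom.coord - c
            ln = np.linalg.norm(v)
            clamped = np.clip(ln, 1.2, 1.8)
            if abs(clamped - ln) > 1e-9:
                shift = v * (clamped / ln - 1.0)
                for atom in nxt.atoms:
                    atom.coord = atom.coord + shift
    return decoy


def randomize_side_chains(model: StructureModel, fraction: float,
                          seed: int = 0) -> StructureModel:
    """Redraw the chi angles of a random fraction of residues uniformly.

    The backbone is untouched bitwise; selected chi-bearing residues get
    side chains rebuilt from uniform chi angles in (-180, 180].
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    out = model.copy()
    rng = np.random.default_rng(seed)
    for res in out.residues():
        n_chi = len(CHI_ATOMS[res.aa_type])
        if n_chi == 0:
            continue
        if rng.random() >= fraction:
            continue
        if any(res.coord(a) is None for a in ("N", "CA", "C")):
            continue
        chis = rng.uniform(-180.0, 180.0, size=n_chi)
        side = place_side_chain(
            res.aa_type, {"N": res.coord("N"), "CA": res.coord("CA"),
                          "C": res.coord("C")}, chis)
        res.atoms = [a for a in res.atoms if a.name in ("N", "CA", "C", "O")] \
            + [Atom(name, name[0], coord) for name, coord in side.items()]
    return out


# ---------------------------------------------------------------------------
# profiles and benchmarks

def make_profile(native: StructureModel, noise_level: float = 0.3,
                 seed: int = 0, spec: MembraneSpec | None = None) -> SequenceProfile:
    """Simulated sequence profile consistent with the native structure.

    PSSM rows are one-hot log-odds of the true sequence blurred by Gaussian
    noise; predicted secondary structure mixes the true assignment with the
    uniform distribution by ``noise_level``; predicted burial is the true
    relative accessibility plus noise; topology follows the true membrane
    region.
    """
    if not 0.0 <= noise_level <= 1.0:
        raise ValueError("noise_level must be in [0, 1]")
    if spec is None:
        spec = MembraneSpec()
    rng = np.random.default_rng(seed)
    residues = native.residues()
    L = len(residues)
    seq = "".join(r.one_letter for r in residues)
    from ._chem import AA_ONE
    pssm = np.full((L, 20), -1.0)
    for i, aa in enumerate(seq):
        pssm[i, AA_ONE.index(aa)] = 5.0
    pssm += noise_level * rng.normal(0.0, 3.0, size=pssm.shape)

    ss = assign_secondary_structure(native)
    onehot = np.zeros((L, 3))
    for i, lab in enumerate(ss):
        onehot[i, {"H": 0, "E": 1, "C": 2}[lab]] = 1.0
    pred_ss = (1.0 - noise_level) * onehot + noise_level / 3.0

    sasa = shrake_rupley_sasa(native)
    burial = np.clip(sasa.relative + noise_level * rng.normal(0.0, 0.2, size=L),
                     0.0, 1.0)

    depths, regions = membrane_depth(native, spec)
    topo = []
    for res, region in zip(residues, regions):
        if region == "core":
            topo.append("membrane")
        else:
            ca = res.coord("CA")
            z = float(np.dot(ca, spec.normal_axis)) if ca is not None else 0.0
            topo.append("inside" if z < 0 else "outside")
    return SequenceProfile(seq, pssm, pred_ss, burial, topo)


def make_benchmark(n_targets: int, n_models_per_target: int, seed: int = 0,
                   n_helices: int = 3, helix_len: int = 12,
                   noise_level: float = 0.3,
                   magnitudes=(0.5, 1.0, 2.0, 4.0, 8.0),
                   max_retries: int = 5) -> list:
    """Seeded multi-target decoy benchmark with known true TM-scores.

    Each target is a fresh helix bundle; its decoys cycle through the
    backbone-perturbation magnitude grid and additionally have a random
    fraction (uniform in [0.3, 1.0]) of side chains randomized.  Targets
    are regenerated (bounded retries) until decoys span a TM spread >= 0.2
    and a chi-correctness spread >= 0.2.
    """
    if n_targets < 1 or n_models_per_target < 2:
        raise ValueError("need n_targets >= 1 and n_models_per_target >= 2")
    from .geometry_eval import chi_correctness
    rng = np.random.default_rng(seed)
    targets = []
    for t in range(n_targets):
        for attempt in range(max_retries):
            tseed = int(rng.integers(2 ** 31))
            native = make_helix_bundle(n_helices, helix_len, seed=tseed,
                                       target_id=f"T{t:02d}")
            profile = make_profile(native, noise_level, seed=tseed + 1)
            models = {}
            true_tm = {}
            chis = []
            for m in range(n_models_per_target):
                # spread decoys evenly across the magnitude grid so even
                # small decoy sets span the full quality range
                mag = magnitudes[m * len(magnitudes) // n_models_per_target]
                mseed = int(rng.integers(2 ** 31))
                decoy = perturb_backbone(native, mag, seed=mseed)
                # stratified draw over [0.3, 1.0]: every decoy set covers the
                # whole side-chain degradation range
                lo = 0.3 + 0.7 * m / n_models_per_target
                hi = 0.3 + 0.7 * (m + 1) / n_models_per_target
                frac = float(rng.uniform(lo, hi))
                decoy = randomize_side_chains(decoy, frac, seed=mseed + 1)
                decoy.model_id = f"m{m:03d}"
                decoy.target_id = native.target_id
                models[decoy.model_id] = decoy
                true_tm[decoy.model_id] = tm_score(decoy, native).score
                chis.append(chi_correctness(decoy, native))
            tm_vals = np.array(list(true_tm.values()))
            if tm_vals.max() - tm_vals.min() >= 0.2 and \
                    max(chis) - min(chis) >= 0.2:
                targets.append(SyntheticTarget(
                    target_id=native.target_id, native=native, models=models,
                    true_tm=true_tm, profile=profile,
                    provenance={"seed": tseed, "n_helices": n_helices,
                                "helix_len": helix_len,
                                "noise_level": noise_level,
                                "magnitudes": tuple(magnitudes),
                                "attempt": attempt}))
                break
        else:
            raise RuntimeError(
                f"target {t}: could not achieve the required decoy spread "
                f"in {max_retries} attempts")
    return targets
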