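"""Geometric primitives and evaluation metrics.

Implements the quantities used to benchmark model selection: torsion angles
(IUPAC sign convention), Kabsch superposition, TM-score with its standard
``d0`` normalization, side-chain chi angles and the chi1/chi2-within-threshold
correctness fraction, and per-target Z-scores of selected models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._chem import CHI_ATOMS, CHI_SYMMETRIC
from .model_io import Residue, StructureModel

__all__ = [
    "Transform",
    "TMScoreResult",
    "ChiRecord",
    "ZScoreResult",
    "dihedral",
    "place_atom",
    "kabsch_superpose",
    "tm_score",
    "tm_d0",
    "compute_chi_angles",
    "chi_correctness",
    "circular_difference",
    "z_scores",
]


@dataclass
class Transform:
    """Rigid transform y = R x + t (rotation proper, det +1)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class TMScoreResult:
    score: float
    d0: float
    n_common: int
    transform: Transform
    per_residue_d: np.ndarray


@dataclass
class ChiRecord:
    residue_id: tuple
    chi: list  # float (degrees) or None where atoms are missing
    symmetric_flags: list  # bool per angle
    missing_flags: list  # bool per angle


@dataclass
class ZScoreResult:
    per_target: dict  # target -> Z of the first-ranked model
    total: float
    selected: dict  # target -> selected model id


# ---------------------------------------------------------------------------
# primitives

def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle in degrees, range (-180, 180], IUPAC sign convention.

    Looking from p2 to p3, a clockwise rotation of the far bond relative to
    the near bond is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = _cross3(b1, b2)
    n2 = _cross3(b2, b3)
    b2n = float(np.sqrt(b2 @ b2))
    if b2n < 1e-9 or n1 @ n1 < 1e-18 or n2 @ n2 < 1e-18:
        raise ValueError("degenerate geometry: collinear or coincident points")
    m1 = _cross3(n1, b2 / b2n)
    angle = np.degrees(np.arctan2(m1 @ n2, n1 @ n2))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place a new atom D from internal coordinates (NeRF construction).

    ``bond`` = |C-D|, ``angle`` = angle(B, C, D) in degrees, ``torsion`` =
    dihedral(A, B, C, D) in degrees.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        -bond * np.sin(ang) * np.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise ValueError("degenerate reference frame for atom placement")
    n /= nn
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def kabsch_superpose(X: np.ndarray, Y: np.ndarray) -> tuple[Transform, float]:
    """Least-squares rigid superposition of X onto Y (reflections excluded).

    Returns the optimal transform and the minimal RMSD.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("coordinate sets must be equal-shape (n, 3) arrays")
    if X.shape[0] < 3:
        raise ValueError("at least 3 points required")
    xc = X.mean(axis=0)
    yc = Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    diff = (X @ R.T + t) - Y
    rmsd = float(np.sqrt((diff ** 2).sum() / X.shape[0]))
    return Transform(R, t), rmsd


# ---------------------------------------------------------------------------
# TM-score

def tm_d0(length: int) -> float:
    """Length-dependent TM-score normalization distance (floored at 0.5 A)."""
    if length > 15:
        d0 = 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = 0.5
    return max(0.5, d0)


def _common_ca(model: StructureModel, reference: StructureModel):
    ref_ca = {}
    for key, res in zip(reference.residue_keys(), reference.residues()):
        ca = res.coord("CA")
        if ca is not None:
            ref_ca[key] = ca
    mod = []
    ref = []
    for key, res in zip(model.residue_keys(), model.residues()):
        ca = res.coord("CA")
        if ca is not None and key in ref_ca:
            mod.append(ca)
            ref.append(ref_ca[key])
    return np.array(mod), np.array(ref)


def tm_score(model: StructureModel, reference: StructureModel,
             max_iter: int = 20) -> TMScoreResult:
    """TM-score of ``model`` against ``reference``.

    Residue correspondence is by (chain, residue number, insertion code).
    The score is maximized over rigid superpositions with an iterative-seed
    heuristic: contiguous seed fragments of several lengths are superposed,
    then the included-residue set is refined under a distance cutoff until
    stable; the best score over all seeds and iterations is reported.
    Normalization uses the reference length.
    """
    X, Y = _common_ca(model, reference)
    n = len(X)
    if n < 5:
        raise ValueError(f"need at least 5 common CA atoms, got {n}")
    L = reference.n_residues()
    d0 = tm_d0(L)
    d0_sq = d0 * d0
    cutoff_later = min(8.0, max(4.5, d0 + 1.0))

    best_score = -1.0
    best_transform = Transform.identity()

    def eval_transform(tr_R, tr_t):
        nonlocal best_score, best_transform
        d_sq = (((X @ tr_R.T + tr_t) - Y) ** 2).sum(axis=1)
        score = float((1.0 / (1.0 + d_sq / d0_sq)).sum() / L)
        if score > best_score:
            best_score = score
            best_transform = Transform(tr_R, tr_t)
        return d_sq

    seed_lengths = sorted({n, max(4, n // 2), max(4, n // 4)}, reverse=True)
    stride = max(1, n // 20)
    for seed_len in seed_lengths:
        for start in range(0, n - seed_len + 1, stride):
            idx = np.arange(start, start + seed_len)
            try:
                tr, _ = kabsch_superpose(X[idx], Y[idx])
            except (ValueError, np.linalg.LinAlgError):
                continue
            included = idx
            for it in range(max_iter):
                d_sq = eval_transform(tr.rotation, tr.translation)
                cutoff = 8.0 if it == 0 else cutoff_later
                new_inc = np.nonzero(d_sq < cutoff * cutoff)[0]
                if len(new_inc) < 4:
                    break
                if len(new_inc) == len(included) and np.array_equal(new_inc, included):
                    break
                included = new_inc
                try:
                    tr, _ = kabsch_superpose(X[included], Y[included])
                except (ValueError, np.linalg.LinAlgError):
                    break

    d_final = np.sqrt((((X @ best_transform.rotation.T + best_transform.translation)
                        - Y) ** 2).sum(axis=1))
    return TMScoreResult(score=best_score, d0=d0, n_common=n,
                         transform=best_transform, per_residue_d=d_final)


# ---------------------------------------------------------------------------
# chi angles

def compute_chi_angles(residue: Residue) -> ChiRecord:
    """Measure the side-chain chi angles a residue's heavy atoms define.

    Angles whose atoms are missing are recorded as ``None`` and flagged;
    two-fold symmetric terminal angles (ASP chi2, GLU chi3, PHE/TYR chi2)
    are flagged symmetric.
    """
    defs = CHI_ATOMS[residue.aa_type]
    sym = CHI_SYMMETRIC.get(residue.aa_type, frozenset())
    chi: list = []
    missing: list = []
    for i, quad in enumerate(defs):
        coords = [residue.coord(name) for name in quad]
        if any(c is None for c in coords):
            chi.append(None)
            missing.append(True)
        else:
            chi.append(dihedral(*coords))
            missing.append(False)
    return ChiRecord(
        residue_id=(residue.seq_number, residue.insertion_code),
        chi=chi,
        symmetric_flags=[i in sym for i in range(len(defs))],
        missing_flags=missing,
    )


def circular_difference(a: float, b: float) -> float:
    """Absolute circular difference of two angles, in [0, 180] degrees."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def chi_correctness(model: StructureModel, reference: StructureModel,
                    threshold: float = 40.0, per_residue: bool = False) -> float:
    """Fraction of chi1/chi2 angles within ``threshold`` degrees of reference.

    Residues are matched by (chain, number, insertion code).  chi1 and chi2
    counts are pooled by default (``per_residue=True`` averages per-residue
    fractions instead).  Symmetric angles take the smaller of the direct and
    180-degree-flipped difference.  Angles missing in either structure are
    excluded.
    """
    ref_res = dict(zip(reference.residue_keys(), reference.residues()))
    n_ok = 0
    n_tot = 0
    fractions = []
    for key, res in zip(model.residue_keys(), model.residues()):
        ref = ref_res.get(key)
        if ref is None or ref.aa_type != res.aa_type:
            continue
        rec_m = compute_chi_angles(res)
        rec_r = compute_chi_angles(ref)
        ok = tot = 0
        for i in range(min(2, len(rec_m.chi))):  # chi1 and chi2 only
            am, ar = rec_m.chi[i], rec_r.chi[i]
            if am is None or ar is None:
                continue
            d = circular_difference(am, ar)
            if rec_m.symmetric_flags[i]:
                d = min(d, 180.0 - d)
            tot += 1
            if d < threshold:
                ok += 1
        n_ok += ok
        n_tot += tot
        if tot:
            fractions.append(ok / tot)
    if n_tot == 0:
        raise ValueError("no comparable chi angles between model and reference")
    if per_residue:
        return float(np.mean(fractions))
    return n_ok / n_tot


# ---------------------------------------------------------------------------
# Z-scores

def z_scores(score_table: dict, quality: dict) -> ZScoreResult:
    """Per-target Z-score of the first-ranked model, summed over targets.

    ``score_table`` maps target -> {model id -> selection score}; ``quality``
    maps target -> {model id -> TM-score}.  The first-ranked model is the
    argmax of the selection score (ties: lexicographically smallest id); its
    quality is standardized against the population mean and standard
    deviation of all models of the target (zero spread gives Z = 0).
    """
    per_target = {}
    selected = {}
    for target, scores in score_table.items():
        if len(scores) < 2:
            raise ValueError(f"target {target!r} has fewer than 2 models")
        q = quality[target]
        first = min(scores, key=lambda m: (-scores[m], m))
        tms = np.array([q[m] for m in sorted(q)], dtype=float)
        std = float(tms.std())  # population std
        if std == 0.0:
            z = 0.0
        else:
            z = float((q[first] - tms.mean()) / std)
        per_target[target] = z
        selected[target] = first
    return ZScoreResult(per_target=per_target,
                        total=float(sum(per_target.values())),
                        selected=selected)
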