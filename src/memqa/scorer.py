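"""Trainable linear per-residue quality predictor.

The per-residue regression target is the S-score of the CA deviation of the
model from the native after global superposition, S(d) = 1 / (1 + (d/d0)^2)
with d0 = 3 A.  The predictor is a ridge-regularized linear map on
z-normalized features, clamped to [0, 1]; the global model score is the mean
over residues.  Training is deterministic (closed-form ridge solution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

MODEL_HEADER = "# MEMQA-MODEL v1"

__all__ = [
    "ScoringModel",
    "QualityPrediction",
    "s_score",
    "predict",
    "train",
    "cross_validate",
    "save_model",
    "load_model",
    "residue_quality_targets",
]


@dataclass
class ScoringModel:
    weights: np.ndarray
    bias: float
    feature_spec: list
    norm_mean: np.ndarray
    norm_std: np.ndarray
    metadata: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.norm_mean = np.asarray(self.norm_mean, dtype=float)
        self.norm_std = np.asarray(self.norm_std, dtype=float)
        k = len(self.feature_spec)
        if not (self.weights.shape == self.norm_mean.shape
                == self.norm_std.shape == (k,)):
            raise ValueError("weights/normalization must match feature_spec length")
        if np.any(self.norm_std <= 0):
            raise ValueError("normalization standard deviations must be positive")


@dataclass
class QualityPrediction:
    per_residue: np.ndarray

    @property
    def global_score(self) -> float:
        return float(self.per_residue.mean())


def s_score(distance, d0: float = 3.0):
    """Distance-to-quality transform 1 / (1 + (d/d0)^2), in (0, 1]."""
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = 1.0 / (1.0 + (d / d0) ** 2)
    return float(out) if out.ndim == 0 else out


def residue_quality_targets(model, reference, d0: float = 3.0) -> np.ndarray:
    """Per-residue training targets: S-score of the CA deviation from the
    reference after one global superposition of the model onto it.

    Residues without a reference counterpart get target 0.  Returned array
    aligns with ``model.residues()``.
    """
    from .geometry_eval import kabsch_superpose
    ref_ca = {}
    for key, res in zip(reference.residue_keys(), reference.residues()):
        ca = res.coord("CA")
        if ca is not None:
            ref_ca[key] = ca
    keys = model.residue_keys()
    mod, ref, idx = [], [], []
    for i, (key, res) in enumerate(zip(keys, model.residues())):
        ca = res.coord("CA")
        if ca is not None and key in ref_ca:
            mod.append(ca)
            ref.append(ref_ca[key])
            idx.append(i)
    if len(mod) < 3:
        raise ValueError("fewer than 3 corresponding CA atoms")
    tr, _ = kabsch_superpose(np.array(mod), np.array(ref))
    d = np.linalg.norm(tr.apply(np.array(mod)) - np.array(ref), axis=1)
    out = np.zeros(model.n_residues())
    out[np.array(idx)] = s_score(d, d0)
    return out


def predict(features: FeatureMatrix, model: ScoringModel) -> QualityPrediction:
    """Per-residue quality in [0, 1] and its mean as the global score."""
    if features.columns != model.feature_spec:
        diff = [c for c in features.columns if c not in set(model.feature_spec)]
        diff += [c for c in model.feature_spec if c not in set(features.columns)]
        raise ValueError(
            f"feature spec mismatch; divergent columns: {diff[:5]}"
            + ("..." if len(diff) > 5 else ""))
    z = (features.values - model.norm_mean) / model.norm_std
    raw = z @ model.weights + model.bias
    return QualityPrediction(np.clip(raw, 0.0, 1.0))


def train(training_pairs, regularization: float = 1.0,
          metadata: str = "") -> ScoringModel:
    """Fit the linear predictor by ridge regression.

    ``training_pairs`` is a sequence of (FeatureMatrix, per-residue targets)
    with a consistent feature spec.  Targets are clamped to [0, 1].
    Normalization constants are fitted on the pooled training rows and
    stored with the model; all-constant columns are dropped (weight 0) with
    a warning.
    """
    pairs = list(training_pairs)
    if not pairs:
        raise ValueError("no training pairs")
    if regularization <= 0:
        raise ValueError("regularization must be positive")
    spec = pairs[0][0].columns
    for fm, _ in pairs:
        if fm.columns != spec:
            raise ValueError("inconsistent feature specs in training data")
    X = np.vstack([fm.values for fm, _ in pairs])
    y = np.concatenate([np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
                        for _, t in pairs])
    if X.shape[0] != y.shape[0]:
        raise ValueError("targets must align with feature rows")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    constant = std < 1e-12
    if np.any(constant):
        logger.warning("dropping %d all-constant feature column(s)",
                       int(constant.sum()))
        std = np.where(constant, 1.0, std)
    Z = (X - mean) / std
    ridge = Ridge(alpha=regularization, fit_intercept=True, solver="cholesky")
    ridge.fit(Z, y)
    weights = np.where(constant, 0.0, ridge.coef_)
    return ScoringModel(weights=weights, bias=float(ridge.intercept_),
                        feature_spec=list(spec), norm_mean=mean, norm_std=std,
                        metadata=metadata)


def cross_validate(pairs_by_target: dict, regularization: float = 1.0,
                   n_folds: int = 5):
    """K-fold cross-validation splitting by target (never within a target).

    ``pairs_by_target`` maps target id -> list of (FeatureMatrix, targets).
    Returns a list of per-fold Pearson correlations between predicted and
    true per-residue quality.
    """
    targets = sorted(pairs_by_target)
    if len(targets) < n_folds:
        raise ValueError("need at least as many targets as folds")
    folds = [targets[i::n_folds] for i in range(n_folds)]
    correlations = []
    for held_out in folds:
        train_pairs = [p for t in targets if t not in held_out
                       for p in pairs_by_target[t]]
        model = train(train_pairs, regularization)
        preds, truth = [], []
        for t in held_out:
            for fm, y in pairs_by_target[t]:
                preds.append(predict(fm, model).per_residue)
                truth.append(np.clip(np.asarray(y, dtype=float), 0.0, 1.0))
        p = np.concatenate(preds)
        q = np.concatenate(truth)
        correlations.append(float(np.corrcoef(p, q)[0, 1]))
    return correlations


def save_model(model: ScoringModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(MODEL_HEADER + "\n")
        fh.write(f"metadata\t{model.metadata}\n")
        fh.write(f"bias\t{float(model.bias)!r}\n")
        for name, w, m, s in zip(model.feature_spec, model.weights,
                                 model.norm_mean, model.norm_std):
            fh.write(f"col\t{name}\t{float(w)!r}\t{float(m)!r}\t{float(s)!r}\n")


def load_model(path) -> ScoringModel:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != MODEL_HEADER:
        raise ValueError(f"{path}: not a {MODEL_HEADER!r} file")
    metadata = ""
    bias = None
    spec, weights, means, stds = [], [], [], []
    for ln in lines[1:]:
        if not ln:
            continue
        parts = ln.split("\t")
        if parts[0] == "metadata":
            metadata = parts[1] if len(parts) > 1 else ""
        elif parts[0] == "bias":
            bias = float(parts[1])
        elif parts[0] == "col":
            if len(parts) != 5:
                raise ValueError(f"{path}: truncated column line: {ln!r}")
            spec.append(parts[1])
            weights.append(float(parts[2]))
            means.append(float(parts[3]))
            stds.append(float(parts[4]))
        else:
            raise ValueError(f"{path}: unknown record {parts[0]!r}")
    if bias is None or not spec:
        raise ValueError(f"{path}: incomplete model file")
    return ScoringModel(np.array(weights), bias, spec,
                        np.array(means), np.array(stds), metadata)
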