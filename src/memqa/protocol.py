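"""The resample-and-rescore selection pipeline.

Each candidate model's side chains are resampled ``n`` times on the fixed
backbone, every decoy is rescored, and the model is assigned the best score
over {original, decoys} (max aggregation: resampling can only rescue a
model, never demote it).  Models are ranked per target by assigned score
and selection power is measured by the summed Z-score of first-ranked
models.  A consensus baseline (mean pairwise TM-score) is included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import MembraneSpec, SequenceProfile, build_feature_matrix, \
    membrane_depth, residue_contact_counts, assign_secondary_structure
from .geometry_eval import chi_correctness, tm_score, z_scores, ZScoreResult
from .model_io import StructureModel
from .repack import PackingParams, RotamerLibrary, generate_decoys
from .scorer import ScoringModel, predict, residue_quality_targets, train

__all__ = [
    "ModelRecord",
    "SelectionResult",
    "BenchmarkResult",
    "resample_and_score",
    "rank_models",
    "consensus_score",
    "run_benchmark",
    "train_from_benchmark",
    "benchmark_inputs",
]


def train_from_benchmark(bench_targets, regularization: float = 1.0,
                         spec: MembraneSpec | None = None) -> ScoringModel:
    """Train the scorer on a synthetic benchmark (decoys vs their natives)."""
    if spec is None:
        spec = MembraneSpec()
    pairs = []
    for t in bench_targets:
        for mid in sorted(t.models):
            model = t.models[mid]
            fm = build_feature_matrix(model, t.profile, spec)
            y = residue_quality_targets(model, t.native)
            pairs.append((fm, y))
    return train(pairs, regularization,
                 metadata=f"synthetic benchmark, {len(bench_targets)} targets")


def benchmark_inputs(bench_targets) -> tuple[dict, dict]:
    """Convert SyntheticTarget list to run_benchmark inputs plus true TM."""
    targets = {t.target_id: (t.native, t.models, t.profile)
               for t in bench_targets}
    quality = {t.target_id: dict(t.true_tm) for t in bench_targets}
    return targets, quality


@dataclass
class ModelRecord:
    model_id: str
    original_score: float
    decoy_scores: list
    assigned_score: float
    best_decoy_id: int | None   # 1-based decoy index, None if no decoys
    chi_before: float | None = None
    chi_after: float | None = None
    true_tm: float | None = None


@dataclass
class SelectionResult:
    records: dict       # model id -> ModelRecord
    ranking: list       # model ids, best first
    first_ranked: str


@dataclass
class BenchmarkResult:
    z_original: ZScoreResult
    z_resampled: ZScoreResult
    z_consensus: ZScoreResult | None
    per_target: dict                 # target -> SelectionResult
    chi_before_mean: float
    chi_after_mean: float
    chi_before_std: float
    chi_after_std: float
    fraction_improved: float
    improvement_targets: list
    no_improvement_targets: list
    set_stats: dict = field(default_factory=dict)  # set name -> stats dict


def resample_and_score(model: StructureModel, profile: SequenceProfile,
                       scorer_model: ScoringModel,
                       library: RotamerLibrary | None = None,
                       params: PackingParams | None = None,
                       spec: MembraneSpec | None = None,
                       n: int = 10, base_seed: int = 0,
                       aggregation: str = "max",
                       keep_decoys: bool = False):
    """Resample a model's side chains ``n`` times and rescore every decoy.

    Sequence features are fixed (computed once per target); structural
    features are recomputed per decoy.  The assigned score aggregates the
    original score and the decoy scores (``max`` by default, ``mean``
    optional).  Deterministic given ``base_seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if aggregation not in ("max", "mean"):
        raise ValueError("aggregation must be 'max' or 'mean'")
    if spec is None:
        spec = MembraneSpec()
    original = predict(build_feature_matrix(model, profile, spec),
                       scorer_model).global_score
    decoys = generate_decoys(model, n=n, base_seed=base_seed,
                             library=library, params=params, spec=spec)
    # features identical across decoys of one backbone
    shared = {
        "obs_ss": assign_secondary_structure(decoys[0].model),
        "depth_region": membrane_depth(decoys[0].model, spec),
        "res_contacts": residue_contact_counts(decoys[0].model),
    }
    scores = [predict(build_feature_matrix(d.model, profile, spec,
                                           precomputed=shared),
                      scorer_model).global_score for d in decoys]
    if aggregation == "max":
        assigned = max([original] + scores)
    else:
        assigned = float(np.mean([original] + scores))
    best_decoy = int(np.argmax(scores)) + 1
    record = ModelRecord(
        model_id=model.model_id,
        original_score=original,
        decoy_scores=scores,
        assigned_score=assigned,
        best_decoy_id=best_decoy,
    )
    if keep_decoys:
        return record, decoys
    return record


def rank_models(records) -> SelectionResult:
    """Rank one target's models by assigned score (ties: smaller id first)."""
    recs = {r.model_id: r for r in records}
    if len(recs) < 2:
        raise ValueError("need at least 2 models to rank")
    ranking = sorted(recs, key=lambda m: (-recs[m].assigned_score, m))
    return SelectionResult(records=recs, ranking=ranking,
                           first_ranked=ranking[0])


def consensus_score(models: dict) -> dict:
    """Consensus scoring: mean TM-score against all other models.

    ``models`` maps model id -> StructureModel; each model in turn serves
    as the reference for the pairwise scores contributing to its mean.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models for consensus")
    ids = sorted(models)
    out = {}
    for m in ids:
        vals = [tm_score(models[o], models[m]).score for o in ids if o != m]
        out[m] = float(np.mean(vals))
    return out


def run_benchmark(targets: dict, scorer_model: ScoringModel,
                  library: RotamerLibrary | None = None,
                  params: PackingParams | None = None,
                  spec: MembraneSpec | None = None,
                  n: int = 10, base_seed: int = 0,
                  aggregation: str = "max",
                  include_consensus: bool = True,
                  include_chi: bool = True,
                  quality: dict | None = None) -> BenchmarkResult:
    """Full selection benchmark over a map target -> (reference, models, profile).

    Computes sum-Z for original-score, resampled-score and (optionally)
    consensus selection; chi1/chi2 correctness of every model before and
    after resampling (best-scoring decoy); the fraction of models whose
    side chains improved; and the partition of targets into backbone
    improvement / no-improvement sets with per-set chi statistics.
    ``quality`` may supply precomputed true TM-scores per target.
    """
    if spec is None:
        spec = MembraneSpec()
    orig_scores: dict = {}
    resamp_scores: dict = {}
    cons_scores: dict = {}
    qual: dict = {}
    per_target: dict = {}
    chi_before_all, chi_after_all = [], []

    for t_index, (target, (reference, models, profile)) in \
            enumerate(sorted(targets.items())):
        if reference is None:
            raise ValueError(f"target {target!r} has no reference structure")
        if len(models) < 2:
            raise ValueError(f"target {target!r} has fewer than 2 models")
        records = []
        q = dict(quality[target]) if quality is not None else {}
        for m_index, mid in enumerate(sorted(models)):
            model = models[mid]
            seed = base_seed + 10_000 * t_index + 100 * m_index
            record, decoys = resample_and_score(
                model, profile, scorer_model, library, params, spec,
                n=n, base_seed=seed, aggregation=aggregation,
                keep_decoys=True)
            if include_chi:
                record.chi_before = chi_correctness(model, reference)
                best = decoys[record.best_decoy_id - 1].model
                record.chi_after = chi_correctness(best, reference)
            else:
                record.chi_before = record.chi_after = float("nan")
            if mid not in q:
                q[mid] = tm_score(model, reference).score
            record.true_tm = q[mid]
            records.append(record)
            chi_before_all.append(record.chi_before)
            chi_after_all.append(record.chi_after)
        sel = rank_models(records)
        per_target[target] = sel
        orig_scores[target] = {r.model_id: r.original_score for r in records}
        resamp_scores[target] = {r.model_id: r.assigned_score for r in records}
        qual[target] = q
        if include_consensus:
            cons_scores[target] = consensus_score(models)

    z_orig = z_scores(orig_scores, qual)
    z_resamp = z_scores(resamp_scores, qual)
    z_cons = z_scores(cons_scores, qual) if include_consensus else None

    improvement, no_improvement = [], []
    for target in sorted(targets):
        tm_orig = qual[target][z_orig.selected[target]]
        tm_resamp = qual[target][z_resamp.selected[target]]
        (improvement if tm_resamp > tm_orig else no_improvement).append(target)

    chi_before_all = np.array(chi_before_all)
    chi_after_all = np.array(chi_after_all)
    improved = chi_after_all > chi_before_all

    set_stats = {}
    for name, members in (("all", sorted(targets)),
                          ("improvement", improvement),
                          ("no_improvement", no_improvement)):
        before, after = [], []
        for t in members:
            for r in per_target[t].records.values():
                before.append(r.chi_before)
                after.append(r.chi_after)
        set_stats[name] = {
            "chi_before_mean": float(np.mean(before)) if before else float("nan"),
            "chi_after_mean": float(np.mean(after)) if after else float("nan"),
            "chi_before_std": float(np.std(before)) if before else float("nan"),
            "chi_after_std": float(np.std(after)) if after else float("nan"),
            "n_targets": len(members),
            "n_models": len(before),
        }

    return BenchmarkResult(
        z_original=z_orig, z_resampled=z_resamp, z_consensus=z_cons,
        per_target=per_target,
        chi_before_mean=float(chi_before_all.mean()),
        chi_after_mean=float(chi_after_all.mean()),
        chi_before_std=float(chi_before_all.std()),
        chi_after_std=float(chi_after_all.std()),
        fraction_improved=float(improved.mean()),
        improvement_targets=improvement,
        no_improvement_targets=no_improvement,
        set_stats=set_stats,
    )
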