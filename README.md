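# memqa

Single-model quality assessment for membrane-protein structural models,
with selection power boosted by **side-chain resampling**.

## The problem

Structure prediction pipelines generate many alternative models per target
and rely on a model quality assessment program (MQAP) to pick the best one.
Consensus methods score a model by its similarity to the other models of
the same target; they are accurate on average but cannot score a single
model in isolation and tend to miss the best individual model.  A
single-model MQAP predicts quality from the model itself — but a good
backbone wearing badly packed side chains looks bad to any scorer that
reads structural features, so good backbone models are lost.

`memqa` addresses this for α-helical membrane proteins: each candidate
model's side chains are rebuilt *N* times on the fixed backbone using a
backbone-dependent rotamer library and a simplified packing energy, every
repacked decoy is rescored, and the model is ranked by its **best**
resampled score.  Because the backbone never moves, Cα-based quality
measures (TM-score) are exactly invariant — resampling can only repair the
side-chain signal, never change what is being assessed.

## What is inside

| Piece | Contents |
| --- | --- |
| `memqa.model_io` | PDB reading/writing/validation (`StructureModel`) |
| `memqa.geometry_eval` | dihedrals, Kabsch superposition, TM-score with d0 = max(0.5, 1.24·(L−15)^⅓ − 1.8), χ1/χ2 correctness (within 40°, 180°-symmetry aware), per-target Z-scores |
| `memqa.features` | Shrake–Rupley SASA, 3-state secondary structure from Kabsch–Sander H-bond energies, atom/residue contact counts, membrane depth, sequence-profile I/O, windowed feature matrix |
| `memqa.scorer` | trainable linear per-residue quality predictor; target is the S-score S(d) = 1/(1+(d/d₀)²) of the Cα deviation, d₀ = 3 Å |
| `memqa.repack` | backbone-dependent rotamer library, ideal-geometry side-chain builder, packing energy, greedy fixed-backbone repacking |
| `memqa.protocol` | resample → rescore → rank pipeline, consensus baseline, benchmark with sum-Z and χ statistics |
| `memqa.synthetic` | membrane helix-bundle generator, graded backbone decoys, side-chain scrambling, simulated sequence profiles |

Model selection is scored by the summed Z-score of first-ranked models:
per target, Z = (TM_selected − mean TM) / std TM over that target's models,
summed over targets.

## Worked example

```python
from memqa.synthetic import make_benchmark
from memqa.protocol import (benchmark_inputs, run_benchmark,
                            train_from_benchmark)

scorer = train_from_benchmark(make_benchmark(5, 20, seed=100004))
targets, quality = benchmark_inputs(make_benchmark(5, 20, seed=1))
result = run_benchmark(targets, scorer, n=10, base_seed=900002,
                       quality=quality)
print(f"sum-Z original  {result.z_original.total:.2f}")
print(f"sum-Z resampled {result.z_resampled.total:.2f}")
print(f"chi1/chi2 correct: {100 * result.chi_before_mean:.1f}% -> "
      f"{100 * result.chi_after_mean:.1f}%")
```

prints

```
sum-Z original  6.30
sum-Z resampled 6.41
chi1/chi2 correct: 50.7% -> 61.4%
```

Side-chain correctness rises for most models, and selection improves
because models whose backbone is good but whose rotamers were scrambled
recover their score, while genuinely bad backbones do not.  The selection
gain is a statistical effect: it holds across resampling replicates on a
given benchmark, though individual benchmark seeds can buck the trend.

The same pipeline is available from the shell:

```bash
memqa synth benchmark --targets 5 --models 20 --seed 1 --out bench/
memqa train --manifest bench/manifest.tsv --out model.tsv
memqa benchmark --manifest bench/manifest.tsv --model model.tsv \
      --n 10 --seed 7 --out report/
```

plus single-model commands `memqa validate / tmscore / chiq / features /
score / repack / resample`.

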