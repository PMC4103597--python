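# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `memqa`.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Scope and assumptions

`memqa` targets α-helical membrane-protein models in PDB format.  Models
are assumed pre-oriented with the membrane normal along z and the bilayer
centre at z = 0 (`MembraneSpec`: half core thickness 15 Å, interface width
6 Å); no orientation search is performed.  Only the first `MODEL` block is
read, `HETATM` records are ignored, alternate locations resolve to the
highest-occupancy copy, hydrogens are parsed but excluded from every
feature and energy, and non-standard residues are dropped with a warning.
Residue identity is `(chain, residue number, insertion code)` throughout;
no sequence alignment is attempted.

## Evaluation layer

**TM-score.**  d0 = max(0.5, 1.24·(L−15)^⅓ − 1.8), L = reference length;
the 0.5 Å floor covers short chains.  The score is maximized over rigid
superpositions with an iterative-seed heuristic: contiguous seed windows of
lengths {L, L/2, L/4} (minimum 4) at stride max(1, L/20) are superposed by
Kabsch SVD; residues within a cutoff (8 Å on the first iteration, then
min(8, max(4.5, d0+1)) Å) are kept and re-superposed until the included set
is stable (20-iteration cap).  The best score over every transform
evaluated is reported, which guarantees the heuristic never scores below
the single all-residue superposition.  Exactness of the global maximum is
not claimed; the suite asserts self-identity, rigid invariance and the
lower bound instead.

**χ1/χ2 correctness.**  Fraction of χ1 and χ2 angles (pooled over all
residues and both angles) whose circular difference to the reference is
below 40°; two-fold-symmetric terminal angles (ASP χ2, GLU χ3, PHE/TYR χ2)
take the smaller of the direct and 180°-flipped difference.  A per-residue
averaged variant is available (`per_residue=True`); pooling is the default
because it is deterministic under missing angles.

**Z-scores.**  Per target, the first-ranked model (argmax of the selection
score, ties to the lexicographically smallest id) is standardized against
the population mean and standard deviation of the target's true TM-scores;
zero spread defines Z = 0.  No outlier trimming.  Population (not sample)
standard deviation, documented here because either convention is defensible.

## Structural features

* **SASA** — Shrake–Rupley with 960 golden-spiral points per atom, probe
  1.4 Å, Chothia/Naccess-style radii (C 1.87, N 1.65, O 1.40, S 1.85 Å).
  Relative accessibility divides residue SASA by a Gly-X-Gly maximum table.
  Sphere points are fixed in the laboratory frame, so SASA (and features
  derived from it) carries ~1% orientation-dependent sampling noise; the
  rigid-invariance test uses a matching tolerance.
* **Secondary structure** — amide hydrogens are reconstructed on N opposite
  the preceding carbonyl; the Kabsch–Sander electrostatic energy
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol defines an
  H-bond at E < −0.5.  H marks residues inside two consecutive i→i+4 turns,
  E marks bridge partners (parallel and antiparallel, chain-boundary
  aware), everything else (including incomplete backbones) is C.  Three
  states suffice for the feature role; DSSP's eight states are not
  reproduced.
* **Contacts** — atom–atom: heavy atoms of other residues (sequence
  separation > 1) within 4.5 Å of any atom of the residue, binned by a
  declared 13-class atom typing (aliphatic/aromatic/carbonyl/carboxylate/
  guanidinium/α carbons, amide/positive/aromatic nitrogens, hydroxyl/
  carbonyl/carboxylate oxygens, sulfur).  Residue–residue: CB–CB (CA for
  GLY) within 8 Å, binned by partner amino acid.  Both cutoffs are
  half-open ([0, cutoff)).
* **Membrane depth** — |z of Cα| with region labels core (< 15 Å),
  interface (< 21 Å), water.

## Feature matrix and scorer

Per residue the base vector concatenates PSSM (20), predicted secondary
structure (3), predicted burial (1), observed secondary structure one-hot
(3), relative SASA (1), membrane depth and region one-hot (4), atom-contact
classes (13) and residue-contact types (20) — 65 values — over a symmetric
window of 9 residues, zero-padded at chain ends with one terminus-indicator
column per offset (594 columns total).  The window size is a package
default; the feature specification is stored with every trained model and
checked at prediction time.

The scorer is a ridge-regularized linear map on z-normalized columns,
clamped to [0, 1]; the global model score is the residue mean.  A linear
model was chosen over a kernel machine deliberately: at this feature width
it is equally expressive in practice, trains in closed form, and is exactly
reproducible.  The per-residue regression target is the S-score
S(d) = 1/(1+(d/3 Å)²) of the Cα deviation after one global superposition of
the model onto its reference.  Cross-validation folds split by target, never
within one, to avoid leakage between decoys of the same protein.
All-constant feature columns are dropped (weight 0) with a warning.

## Side-chain resampling

**Rotamer library.**  Rotamers live in 30° (φ, ψ) bins with a
backbone-independent fallback for unpopulated bins and undefined termini.
The built-in minimal library crosses canonical per-χ states (χ1 at
−65/180/62°, sp³ χ2 trans-dominant, aromatic χ2 ±90°, PRO's two correlated
ring puckers, distal χ of ARG/LYS/MET fixed at trans) with helix- and
sheet-region bins re-weighting the χ1 preference; richer libraries load
from a documented TSV.  Probabilities are normalized per bin.

**Side-chain builder.**  Ideal internal geometry (textbook bond lengths and
angles, CB placed at the L-configuration improper torsion +120° from
C-N-CA) via NeRF placement; measuring χ of placed atoms reproduces the
inputs to numerical precision, which the suite asserts for all 18
χ-bearing types.  Ring closure for 5-membered rings is approximate (PRO's
CD is built from χ2, not closed onto N) — adequate for packing and χ
statistics, not for covalent-geometry analysis.

**Packing energy.**  Three additive terms: a soft-sphere steric penalty
Σ max(0, 0.8·(rᵢ+rⱼ) − d)² over inter-residue heavy-atom pairs involving a
side-chain atom (covalently constrained CB/backbone pairs of adjacent
residues excluded); a rotamer term −ln p of the nearest library rotamer;
and a hydropathy-mismatch term (polar residues penalized in the membrane
core, hydrophobic in water; Kyte–Doolittle scale normalized by 4.5).
Default weights 1.0 / 0.2 / 0.1.  This is a deliberately simplified packing
score — its only job is that minimizing it improves side-chain packing;
fidelity to any full molecular-mechanics energy is a non-goal.

**Repacking.**  Each χ-bearing residue with a complete backbone starts at
its bin's most probable rotamer; residues are then swept in seeded random
order, greedily accepting the lowest-local-energy candidate (current
conformation included), until a sweep changes nothing (10-sweep cap).
Greedy descent is the default for determinism and testability; seeded
Metropolis annealing with a geometric temperature schedule (followed by a
greedy quench) is available via `PackingParams(anneal=True)`.  Because
initialization ignores the input side chains, the
repacked state depends only on (backbone, library, seed), which makes
repacking idempotent at fixed seed and makes decoy generation (seeds
base+1 … base+n) bit-reproducible.  Backbone atoms are never touched.
Optional Gaussian χ jitter around rotamer means (library σ, seeded) is off
by default: decoy diversity comes from sweep-order randomness.

**Resample-and-rescore.**  Each model gets n = 10 decoys (the default
follows the observation that selection gain saturates around ten
resamples); sequence features are computed once per target, structural
features per decoy (backbone-only features — secondary structure, membrane
depth, CB contacts — are shared across a model's decoys, since all decoys
carry the identical backbone and CB).  The assigned score is the **max**
over {original, decoys}: the combiner is monotone in n and matches the
rescue rationale — a good backbone with bad side chains needs only one
well-packed decoy to be recognized; a mean combiner is available behind a
flag.  The consensus baseline scores each model by the mean TM-score of all
other models against it.

## Synthetic benchmark

The generator provides the controlled conditions the selection claims need;
it does not attempt folding realism.

* **Natives** — ideal α-helices (φ = −57°, ψ = −47°) placed on a circle
  (radius ≈ 10 Å / 2 sin(π/n), adjacent spacing ~10 Å), alternating
  up/down, joined by short Hermite-interpolated loops whose C/N atoms are
  solved to peptide bond lengths; side chains at most-probable rotamers;
  hydrophobic-biased sequence in the membrane span, polar loops.  Backbone
  geometry is deterministic given the architecture; the seed drives
  sequence and decoys.
* **Decoys** — a Gaussian-smoothed (σ = 5 residues) random displacement
  field applied rigidly per residue, scaled to RMS = magnitude
  (grid {0.5, 1, 2, 4, 8} Å spread evenly over the decoy set), peptide
  bonds clamped to [1.2, 1.8] Å.  Rigid per-residue displacement preserves
  χ angles exactly, so side-chain degradation is controlled separately:
  a stratified-uniform fraction in [0.3, 1.0] of residues get χ redrawn
  uniformly.  Each target is regenerated (bounded retries) until its decoys
  span ≥ 0.2 in TM and ≥ 0.2 in χ correctness.
* **Profiles** — one-hot log-odds PSSM blurred by Gaussian noise, predicted
  secondary structure mixed with uniform by the noise level, predicted
  burial = true relative SASA plus noise, topology from the true membrane
  region.  Default noise level 0.3.

Benchmark scale is 5 targets × 20 models of 3-helix, 42-residue bundles
with 10 resamples per model and 25 resampling replicates — sizes chosen so
the whole suite runs on a laptop while leaving each target a full quality
gradient.  What passing shows: the pipeline's selection gain operates
through the stated mechanism on data with known structure.  What it does
not show: performance on real decoy sets, β-barrels, models needing
alignment-based correspondence, or profiles from real sequence searches.

## Numerical conventions

Dihedrals follow the IUPAC sign convention, range (−180°, 180°]; circular
differences are reduced to [0°, 180°].  A torsion angle is invariant under
reading the chain backwards and negated by mirror reflection (the property
tests assert exactly this).  Kabsch superposition excludes reflections via
the SVD determinant correction.  Ranking ties break lexicographically by
model id.  Degenerate inputs are represented, not raised, where the science
allows it: missing χ atoms yield flagged absent angles, incomplete
backbones are labelled coil and skipped by the repacker, zero TM spread
yields Z = 0.

## Known limitations

* The minimal rotamer library is intentionally coarse (no distal χ
  diversity for ARG/LYS/MET); repacked χ correctness saturates well below
  what a full statistical library would reach.
* SASA is orientation-dependent at the ~1% sampling level (fixed sphere
  points); doubling the point count on the test bundle moves totals by
  < 0.5%.
* The TM-score search is a heuristic; it is bounded below by the plain
  superposition score but not proven globally optimal.
* Loops in synthetic bundles have correct bond lengths but unphysical
  bond angles; they are labelled coil and carry polar sequence, nothing
  more is asked of them.
* Disulfides are not modelled; PRO repacking uses its two ring-pucker
  rotamers without closing the ring covalently.
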