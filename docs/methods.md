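# Methods

`confactory` re-creates, at desk scale, the data-acquisition machinery of an
active-learning "data factory" for molecular conformational energies: a
committee of energy predictors ranks a stream of candidate conformations,
the most informative candidates are labeled by an oracle and folded back
into training, committee-driven Langevin dynamics generates new off-
equilibrium conformations scored by a force-agreement confidence measure,
and a strict scaffold split guards benchmark evaluation against scaffold
leakage. The expensive quantum-chemical labeler of the production setting
is replaced by a pluggable analytic oracle, so every experiment here runs
in minutes on one CPU.

## The toy labeling oracle

The oracle is a bonded + Lennard-Jones potential over hydrogen-explicit
molecules:

    E(R) = E_ref + Σ_bonds k (d − d0)² + Σ_pairs 4ε[(σ/d)¹² − (σ/d)⁶]

* `k = 300 kcal mol⁻¹ Å⁻²` for every bond; `d0` is the sum of covalent
  radii scaled by a bond-order factor (1.0 / 0.93 / 0.87 / 0.78 for
  single / aromatic / double / triple), so distance-geometry conformers
  start near the potential's minimum, as force-field-generated structures
  do in real pipelines.
* Nonbonded pairs exclude 1-2 and 1-3 neighbours; ε, σ come from a small
  per-element table with Lorentz-Berthelot combination.
* `E_ref` is a sum of per-element reference constants (large negative
  numbers), emulating the *total-energy* scale on which quantum-chemical
  labels arrive. Conformational energy differences are untouched, but
  relative-standard-deviation disagreement scores — std of committee
  predictions over |mean| — are only meaningful on a scale whose
  denominator does not cross zero, which is exactly the situation with
  total-energy labels.
* Optional Gaussian label noise (default 0.1 kcal/mol in the benchmark,
  mimicking converged-calculation scatter) perturbs reported energies
  only. Forces stay exactly analytic, so force-consistency tests are exact
  and the oracle can drive reference dynamics.

Energy and forces are analytically consistent to first order; the test
suite verifies forces against central finite differences at 1e-4 relative
tolerance.

## The built-in predictor

`RBFPairRegressor` is a linear model over per-edge radial-basis features.
An atom pair is an edge of the conformation graph if it is covalently
bonded (at any distance) or closer than a 4 Å threshold. Each edge
contributes a Gaussian expansion of its distance (`n_centers` basis
functions over 0.7–4 Å) into a weight block indexed by (element-pair
class, bonded flag); per-element atom counts provide linear
energy-shifter terms. Element-pair blocks use a seven-class alphabet
(H, C, N, O, F, heavier halogens, S/other): a block's weight curve is a
free function of distance, so merged elements whose pair-distance
distributions occupy different ranges coexist in one block, and the
reduced feature dimension (~10³) keeps hundreds of closed-form retrains
inside a test-suite budget.
The energy-shifter terms are per *element*, not per class — reference
constants must be exactly representable or their residue leaks into the
distance curves.

Three constructions make the model usable as a force field, not just an
interpolator:

1. **Delta-learning on a crude prior.** The model predicts the residual
   against a fixed generic potential (one spring constant for all bonds,
   single-bond equilibrium lengths with no bond-order correction, one LJ
   parameter pair for hydrogens and one for heavy atoms). The prior is
   deliberately too crude to be accurate, but it guarantees a repulsive
   wall at short range and a restoring force at large bond stretch —
   regions the training set cannot cover. Without it, model-driven
   dynamics walks into spurious minima of the learned surface within a
   few femtoseconds.
2. **Curvature penalty.** Training is generalized ridge: the usual L2
   penalty plus a P-spline-style penalty on the integrated squared second
   derivative of every pair-block weight curve (weight 1e-4, evaluated on
   a dense distance grid). An energy-only fit leaves the gradient between
   training distances unconstrained; the curvature term suppresses
   oscillations that would otherwise dominate forces.
3. **Seeded diversity.** `clone_with_seed` jitters the basis-center
   positions (up to ±0.3 of the center spacing) and draws per-example
   Poisson(1) bootstrap weights — the analogs of random initialization
   and data-order stochasticity in neural-network committees. Same-
   configuration committees with different seeds therefore still disagree
   away from their common training support.

Training is closed-form (solve `(XᵀWX + P) w = XᵀWy`), deterministic, and
identical whether performed in one shot or by accumulating Gram-matrix
contributions as the training set grows — the simulation uses the
incremental form, and a unit test asserts the equivalence.

The default heterogeneous committee has five members with basis sizes
24–40, width factors 0.8–1.3 and ridge penalties 1e-6–1e-5, chosen so
members remain data-limited at the simulation's seed size (1000 examples)
and keep learning as acquisitions accumulate; a saturated committee makes
every selection strategy look alike. The homogeneous ("x5") committee is
five copies of a middle configuration differing only by seed.

## Samplers

* `RAND` — seeded uniform shuffle.
* `VAR` — query-by-committee: candidates ranked by the relative standard
  deviation (population std over ε-guarded |mean|, ε = 1e-8) of committee
  energy predictions, descending. With total-energy-scale labels the
  denominator is dominated by the molecule's reference energy, making RSD
  effectively a per-molecule size normalization of the committee std.
  Committee disagreement senses *coverage gaps* — geometries and
  chemistries the training set constrains poorly. It is not a label-noise
  detector: with local distance features, a noisy label at one
  conformation does not move predictions at another conformation of the
  same molecule, so molecule-level label corruption is visible to the
  loss-prediction sampler (which keys on molecular identity) but largely
  invisible to committee variance at unseen conformations. The property
  suite tests each sampler on the signal it can carry: enrichment of
  mislabeled molecules for LOSSFN, rank correlation with realized error
  for VAR.
* `LOSSFN` — loss prediction: for each member, a ridge regression (penalty
  1e-6, with intercept) maps the molecule's 167-bit MACCS fingerprint to
  that member's absolute training error; a candidate's score is the
  member-mean predicted error, clipped at zero. Scores depend on molecular
  identity only, so all conformations of a molecule tie and their relative
  order is the recorded tie-break shuffle. Per-member regression with mean
  aggregation was chosen over regressing the aggregate committee error;
  both are available through the fitted per-member models.

Ties in every strategy are broken by a seeded shuffle applied before a
stable sort, so ranking runs are reproducible.

## Data-stream simulation

Four disjoint sets over the labeled training data: Seed (1000), Buffer
(600), 300 moved per round for 5 rounds, refill equal to the move — a
1:100 scaling of the production protocol (100k/60k/30k). Each round the
committee retrains from scratch on Seed + acquired examples, re-ranks the
Buffer, moves the top 300 into the acquired set and refills the Buffer
from the Pool. The learning curve records held-out MAE per round
(`n_rounds + 1` points including the final retrain).

Comparisons are paired: for a given replicate seed, every strategy starts
from the identical partition *and* sees identical per-round refill draws
(refill randomness depends only on replicate seed and round), so curves
differ only through selection. Curves are averaged over three replicate
seeds.

The curve is evaluated on a fixed 800-conformation sample spanning all
held-out molecules (strict-test plus validation): at this library size the
strict similarity threshold leaves only a handful of test molecules, and a
test-only MAE is dominated by their idiosyncrasies. Validation molecules
are equally unseen during training — the split is by molecule — differing
only in scaffold similarity to the train set. Reported labeled counts are
|Seed| + |acquired| (whether the production protocol's x-axis includes the
seed set is ambiguous; this convention is stated rather than guessed).

## Langevin dynamics and confidence scoring

BAOAB splitting with per-component Maxwell-Boltzmann velocity
initialization at the bath temperature. Units: Å, fs, amu, kcal/mol;
temperature from `T = 2·KE/(k_B·3N)` with no rigid-body-mode removal
(documented so tests are exact). Defaults: 1 fs timestep (forced by the
protocol's 1000 steps = 1 ps), friction 1 ps⁻¹ and bath 300 K (the
protocol states neither). Training mode runs 1 ps saving every 10th frame
with at most 6 selections per trajectory; test mode runs 0.1 ps saving
every frame. Both stop when the instantaneous temperature exceeds a 600 K
cap; the tripping frame is flagged and excluded from frame selection (a
labeling pipeline would reject a diverging structure; including such
frames puts multi-thousand-kcal outliers into a least-squares fit).
The committee's mean-energy gradient supplies forces; the full committee
is used (a member subset is selectable).

The confidence score of a frame: for every atom, the cosine between each
pair of members' force vectors on that atom; the minimum over member pairs;
the mean over atoms. A zero force vector has no direction and scores 0
against anything (flagged in frame diagnostics). A brute-force double-loop
reference implementation lives in the test suite and the vectorized score
must match it to 1e-12.

Minimization evaluation over (initial, final) pairs: Spearman rank
correlation between committee-predicted and true energy differences,
success rate (percentage with a true energy decrease), and mean true
difference. Evaluation MD starts from raw generated (non-MD, non-optimized)
held-out conformations.

## Benchmark assembly

One master seed generates: a 1200-molecule synthetic library (fragment
grammar over ~35 ring cores, ~20 secondary rings, linkers and
substituents, deduplicated by canonical SMILES), a strict scaffold split
(80% train; holdout molecules with scaffold MACCS Tanimoto ≥ 0.7 to any
train scaffold go to validation; the rest form test), ETKDG conformers
(3 per train molecule, 7 per held-out molecule) and an off-equilibrium
stratum (1 per train molecule, 3 per held-out molecule) from 50-step
oracle-driven Langevin runs at a 500 K bath — hot enough that the stratum
carries real displacement information — labeled with 0.1 kcal/mol noise. The mixed
strata mirror the generated/optimized/MD composition of real
conformational-energy datasets; an MMFF-optimized stratum is omitted as it
adds no distinct physics under the toy oracle. Without the MD stratum an
energy-only model sees no bond-displacement signal — all generated
conformers have near-identical bond lengths — and cannot function as a
force field at all.

What the toy setting does not emulate: electronic effects beyond pair
distances (conjugation, charge transfer), conformer populations of real
molecules, labeling cost heterogeneity, and the network/latency dynamics
of a real volunteer fleet. Passing the directional experiments here shows
the *machinery* behaves as designed under a controllable potential, not
that any particular accuracy transfers to quantum-chemical labels.

## MD-sampling experiment

Per replicate: the committee trains on the full benchmark training set;
training-mode trajectories start from random training conformations; the
augmentation budget is 200 frames. The treated arm takes the
lowest-confidence frames (≤ 6 per trajectory); the control arm takes, by
default, freshly generated random conformations of training molecules
(the protocol's "random new examples" control), or — the sharper paired
test of the selection rule itself — uniform random frames from the same
trajectories (`control="frames"`). Both augmentations pass the same label
sanity filter (true energy ≤ 500 kcal/mol). Augmented committees are then
evaluated by test-mode MD from held-out generated conformations with
common random seeds across arms.

## Task protocol

Tasks wrap single conformations as V2000 MOL blocks (4-decimal
coordinates); results are JSON property dictionaries; task volume is the
total atom count. The file-based broker keeps one file per message under
`pending/ claimed/ done/ failed/ quarantine/`; claiming renames
pending→claimed, which is atomic on one filesystem, so concurrent workers
cannot double-claim; FIFO order comes from zero-padded enqueue-time
prefixes; stale claims return to pending after a visible timeout (default
30 min). Verification is fractional task duplication with
relative-tolerance agreement (absolute below 1e-8 magnitude) — the
production system names a "results verification threshold" without
defining mechanics, and this is the simplest semantics consistent with the
name. Batching multiple conformations per task is intentionally not
implemented (single-conformation tasks are the documented unit of work).

## Numerical conventions

* Canonical energy unit: kcal/mol; 1 Hartree = 627.509 kcal/mol, declared
  once in `units.py`.
* `tanimoto(empty, empty) = 0`, avoiding NaN for acyclic-molecule
  scaffolds; acyclic holdout molecules go to validation when the train set
  contains an acyclic molecule, else to test.
* Train count is `round(train_frac · N)`; holdout similarity is
  max-over-train, scaffold-to-scaffold, on MACCS fingerprints of the
  Bemis-Murcko SMILES.
* Conformer embedding seeds are `seed + index`, so prefixes reproduce.
* SDF energy tags are written at full double precision; MOL-block
  coordinates carry 4 decimals with a full-precision companion property
  for lossless dataset round-trips.
* All stochastic components (library grammar, splits, embeddings,
  velocities, tie-breaks, bootstrap weights) derive from explicit integer
  seeds; every seeded operation is bitwise reproducible in one
  environment.

## Known limitations

* The committee's absolute accuracy and its MD stability are those of a
  ~10³-parameter linear model; conclusions are directional orderings, not
  transferable error magnitudes.
* RSD disagreement inherits the scale-dependence of its denominator; on
  strain-energy-scale labels (magnitudes near zero) it is ill-behaved,
  which is why benchmark labels sit on the total-energy scale.
* The strict split at 1200 molecules leaves few test molecules; leakage
  guarantees hold exactly, but test-only metrics are noisy (hence the
  pooled held-out evaluation sample).
* The broker's atomicity relies on POSIX rename semantics within one
  filesystem; spanning filesystems or NFS is untested.
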