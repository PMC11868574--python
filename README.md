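# confactory

Active-learning data acquisition for molecular conformational energies,
at desk scale.

Large labeled datasets of molecular conformations with quantum-chemical
energies are expensive: each label costs CPU-minutes to -hours of DFT.
Distributed data-factory platforms attack the cost from two sides —
volunteer machines perform the calculations, and an ensemble ("committee")
of ML energy predictors decides *which* conformations are worth labeling
at all. `confactory` implements that decision machinery as a tested
Python library and CLI, with the DFT labeler replaced by a pluggable
analytic oracle so the entire pipeline runs in minutes on a laptop:

* **`molkit`** — molecule/conformation types, Bemis-Murcko scaffolds,
  MACCS fingerprints, ETKDGv3/MMFF94 conformer generation, SDF/CSV/XYZ
  I/O, a deterministic synthetic library of drug-like molecules, and the
  bonded + Lennard-Jones toy oracle (analytic energies *and* forces).
* **`splitter`** — strict scaffold-and-similarity train/validation/test
  splitting: after an 80% random train draw, any held-out molecule whose
  Bemis-Murcko scaffold has Tanimoto similarity ≥ 0.7 to a train scaffold
  is banished to validation, so **no train-test scaffold pair reaches the
  threshold** — verified by exhaustive scan.
* **`predictors`** — a committee of ridge-trained radial-basis edge
  regressors with analytic forces (delta-learned on a crude physical
  prior), the mean-combining `Ensemble`, and the relative-standard-
  deviation disagreement score.
* **`samplers`** — candidate ranking: `RAND` baseline, query-by-committee
  `VAR` (disagreement), and `LOSSFN` loss prediction (per-member linear
  models mapping MACCS fingerprints to expected error).
* **`stream_sim`** — the Pool/Buffer/Seed data-stream active-learning
  simulation with paired strategy comparisons and learning curves.
* **`md_engine`** — BAOAB Langevin dynamics driven by the committee's
  mean-energy gradient, the per-atom minimum-pairwise-cosine force
  confidence score, low-confidence frame selection, and
  energy-minimization evaluation (Spearman of energy differences, success
  rate, mean delta).
* **`taskfactory`** — the volunteer-computing protocol: MOL-block tasks,
  atom-count volume estimates, a file-based message broker with atomic
  claim semantics, redundant-result verification, and a worker loop.
* **`benchmark`** — one-seed assembly of the full study setup (library →
  split → conformer strata → labels) used by the experiments and tests.

## The core quantities

Committee disagreement for a conformation `x` with member predictions
`E_1..E_M`:

    RSD(x) = std(E_1..E_M) / max(|mean(E_1..E_M)|, 1e-8)

Force-agreement confidence of a structure with per-member atomic forces
`F_m^i`:

    C = (1/N) Σ_i min{ cos∠(F_q^i, F_k^i) : q ≠ k }

Candidates with the highest RSD (or highest fingerprint-predicted error),
and MD frames with the lowest confidence `C`, are the ones sent for
labeling.

## Worked example

```python
import confactory as cf

# 1. A deterministic library and a leakage-proof split
mols = cf.synthetic_library(500, seed=1)
split = cf.scaffold_split(mols, train_frac=0.8, sim_threshold=0.7, seed=2)
print(split.report["n_train"], split.report["n_test"],
      round(split.report["max_train_test_scaffold_tanimoto"], 3))
# 400 8 0.69

# 2. Conformers, toy-oracle labels, a trained committee
train_mols = [m for m in mols if split.assignment()[m.id] == "train"][:100]
confs = [c for m in train_mols for c in cf.generate_conformations(m, 3, seed=3)]
data = cf.label_conformations(confs, noise_std=0.1, seed=4)
ens = cf.train_ensemble(cf.DEFAULT_HETEROGENEOUS_CONFIGS, data, seed=5)
print(round(cf.evaluate(ens, data)["mae"], 2))
# 1.32

# 3. Rank unseen candidates by committee disagreement
pool = [c for m in train_mols[:10] for c in cf.generate_conformations(m, 2, seed=9)]
ranked = cf.rank_candidates("VAR", pool, seed=6, ens=ens)
print(f"{ranked.scores[0]:.2e}", ">=", f"{ranked.scores[-1]:.2e}")
# 2.65e-04 >= 4.35e-05
```

The split line says: of 500 molecules, 400 train, 8 reach the test set,
and the most similar train-test scaffold pair sits at Tanimoto 0.69 —
below the 0.7 threshold the splitter enforces by construction. The
committee's training MAE (kcal/mol) is far below the dataset's energy
spread, and ranking returns pool conformations ordered by disagreement,
most informative first.

The same pipeline is available from the shell:

```bash
confactory split --in mols.smi --train-frac 0.8 --sim-threshold 0.7 --seed 13 --out split.json
confactory train --data train.sdf --seed 1 --out model.ckpt
confactory rank  --strategy lossfn --model model.ckpt --data train.sdf \
                 --candidates pool.sdf --top 300 --seed 2 --out selected.sdf
confactory md    --model model.ckpt --in conf.sdf --mode test --seed 3 --out traj.xyz
confactory serve --spool ./spool --in selected.sdf
confactory work  --spool ./spool --calculator toy --max-tasks 100
```

See `docs/methods.md` for the model, the simulation protocol, and every
numerical convention.

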