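"""Candidate ranking strategies for active data acquisition.

Three strategies are provided:

* ``RAND`` — seeded uniform shuffle (the baseline);
* ``VAR``  — query-by-committee: rank by the relative standard deviation of
  the committee's energy predictions, highest disagreement first;
* ``LOSSFN`` — loss prediction: one linear model per committee member maps
  the molecule's MACCS fingerprint to that member's expected absolute
  energy error; candidates are ranked by the member-mean predicted error.

The loss predictors see only molecular identity (the fingerprint), never
coordinates, so all conformations of one molecule share a score and their
relative order is exactly the seeded tie-break shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge

from .molkit import Conformation, LabeledDataset, Molecule, maccs
from .predictors import Ensemble, disagreement_rsd

STRATEGIES = ("RAND", "VAR", "LOSSFN")


@dataclass
class LossPredictors:
    """Per-member linear error models over MACCS fingerprints."""

    models: list          # one fitted Ridge per ensemble member
    n_members: int
    fit_stats: dict

    def member_scores(self, mol: Molecule) -> np.ndarray:
        x = maccs(mol).as_array()[None, :]
        return np.array([float(m.predict(x)[0]) for m in self.models])


def fit_loss_predictors(ens: Ensemble, data: LabeledDataset,
                        ridge: float = 1e-6) -> LossPredictors:
    """Regress each member's absolute error on the molecule fingerprint.

    Trained on the same dataset as the ensemble, regressing each member's
    in-sample absolute error, per the platform's protocol.  A small ridge
    penalty handles the collinearity of MACCS bits on small molecule sets.
    """
    if len(data) < 2:
        raise ValueError("need at least 2 labeled examples")
    y_true = data.energies_kcal()
    X = np.stack([maccs(c.molecule).as_array() for c in data.entries])
    member_pred = ens.member_energies_batch(data.entries)
    models, stats = [], {}
    for m, pred in enumerate(member_pred):
        target = np.abs(pred - y_true)
        model = Ridge(alpha=ridge, fit_intercept=True)
        model.fit(X, target)
        in_sample = model.predict(X)
        models.append(model)
        stats[f"member_{m}_train_mae"] = float(
            np.mean(np.abs(in_sample - target)))
    return LossPredictors(models=models, n_members=ens.n_members,
                          fit_stats=stats)


def predicted_error_score(lp: LossPredictors, mol: Molecule) -> float:
    """Mean over members of the predicted absolute error, clipped at 0."""
    return float(np.mean(np.clip(lp.member_scores(mol), 0.0, None)))


@dataclass
class RankedCandidates:
    """Conformations ordered most-informative-first."""

    order: list[Conformation]
    scores: np.ndarray
    strategy: str
    seed: int

    def __len__(self):
        return len(self.order)

    def top(self, k: int) -> list[Conformation]:
        return self.order[:k]


def rank_candidates(strategy: str, confs: list[Conformation], seed: int = 0,
                    ens: Ensemble | None = None,
                    lp: LossPredictors | None = None) -> RankedCandidates:
    """Rank candidate conformations under one of the three strategies.

    Scores are sorted descending; ties (including all of RAND, where every
    score is 0) fall back to a seeded shuffle applied before the stable
    sort, so runs are reproducible and within-molecule LOSSFN order is the
    recorded tie-break.
    """
    strategy = strategy.upper()
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected {STRATEGIES}")
    n = len(confs)
    if n == 0:
        raise ValueError("no candidates to rank")

    if strategy == "RAND":
        scores = np.zeros(n)
    elif strategy == "VAR":
        if ens is None:
            raise ValueError("VAR strategy requires a trained ensemble")
        per_member = ens.member_energies_batch(confs)   # M x n
        scores = np.array([disagreement_rsd(per_member[:, j]) for j in range(n)])
    else:  # LOSSFN
        if lp is None:
            raise ValueError("LOSSFN strategy requires fitted loss predictors")
        mol_scores: dict[str, float] = {}
        scores = np.empty(n)
        for j, conf in enumerate(confs):
            mid = conf.molecule.id
            if mid not in mol_scores:
                mol_scores[mid] = predicted_error_score(lp, conf.molecule)
            scores[j] = mol_scores[mid]

    rng = np.random.default_rng(int(seed) % (2**31))
    shuffle = rng.permutation(n)
    # Stable sort on the pre-shuffled arrays: equal scores keep shuffle order.
    within = np.argsort(-scores[shuffle], kind="stable")
    perm = shuffle[within]
    return RankedCandidates(order=[confs[i] for i in perm],
                            scores=scores[perm], strategy=strategy,
                            seed=int(seed))
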