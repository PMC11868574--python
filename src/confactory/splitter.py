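"""Strict scaffold-and-similarity train/validation/test splitting.

The protocol: draw a uniform random train set (``round(train_frac * N)``
molecules), then route every remaining molecule whose Bemis-Murcko scaffold
has Tanimoto similarity >= ``sim_threshold`` to *any* train scaffold into
the validation set; the rest form the test set.  By construction the
maximum train-test scaffold similarity is below the threshold, which is the
leakage guarantee the split exists for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .molkit import Fingerprint, Molecule, bemis_murcko, maccs, tanimoto

DEFAULT_TRAIN_FRAC = 0.8
DEFAULT_SIM_THRESHOLD = 0.7


@dataclass
class Split:
    """Disjoint train/validation/test molecule-id lists plus audit summary."""

    train: list[str]
    validation: list[str]
    test: list[str]
    report: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"train": self.train, "validation": self.validation,
                "test": self.test, "report": self.report}

    def assignment(self) -> dict[str, str]:
        out = {}
        for name in ("train", "validation", "test"):
            for mol_id in getattr(self, name):
                out[mol_id] = name
        return out


def scaffold_fingerprint(mol: Molecule) -> Fingerprint:
    """MACCS fingerprint of the molecule's Bemis-Murcko scaffold."""
    return maccs(bemis_murcko(mol))


def _max_cross_similarity(fps_a: list[Fingerprint], fps_b: list[Fingerprint]
                          ) -> float:
    best = 0.0
    for fa in fps_a:
        for fb in fps_b:
            s = tanimoto(fa, fb)
            if s > best:
                best = s
    return best


def scaffold_split(mols: list[Molecule], train_frac: float = DEFAULT_TRAIN_FRAC,
                   sim_threshold: float = DEFAULT_SIM_THRESHOLD,
                   seed: int = 0) -> Split:
    """Split molecules so no train-test scaffold pair reaches ``sim_threshold``.

    Acyclic molecules carry an empty scaffold, for which pairwise similarity
    is defined as 0; they are routed to validation whenever the train set
    also contains an acyclic molecule (identical "scaffolds"), else to test.
    """
    if len(mols) < 5:
        raise ValueError("need at least 5 molecules to split")
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    if not 0.0 < sim_threshold <= 1.0:
        raise ValueError(f"sim_threshold must be in (0, 1], got {sim_threshold}")

    rng = np.random.default_rng(int(seed))
    n = len(mols)
    n_train = int(round(train_frac * n))
    order = rng.permutation(n)
    train_pos = set(order[:n_train].tolist())

    scaffolds = [bemis_murcko(m) for m in mols]
    fps = [maccs(s) for s in scaffolds]

    train_idx = sorted(train_pos)
    rest_idx = [i for i in range(n) if i not in train_pos]
    train_fps = [fps[i] for i in train_idx]
    train_has_acyclic = any(scaffolds[i].is_empty for i in train_idx)

    val_idx, test_idx = [], []
    for i in rest_idx:
        if scaffolds[i].is_empty:
            (val_idx if train_has_acyclic else test_idx).append(i)
            continue
        best = max((tanimoto(fps[i], tf) for tf in train_fps), default=0.0)
        (val_idx if best >= sim_threshold else test_idx).append(i)

    if not test_idx:
        warnings.warn("test set is empty: every held-out scaffold is within "
                      f"{sim_threshold} similarity of the train set")

    max_tt = _max_cross_similarity([fps[i] for i in train_idx],
                                   [fps[i] for i in test_idx])
    report = {
        "n_molecules": n,
        "n_train": len(train_idx),
        "n_validation": len(val_idx),
        "n_test": len(test_idx),
        "unique_scaffolds": {
            name: len({scaffolds[i].smiles for i in idx})
            for name, idx in (("train", train_idx), ("validation", val_idx),
                              ("test", test_idx))
        },
        "max_train_test_scaffold_tanimoto": max_tt,
        "sim_threshold": sim_threshold,
    }
    return Split(train=[mols[i].id for i in train_idx],
                 validation=[mols[i].id for i in val_idx],
                 test=[mols[i].id for i in test_idx],
                 report=report)


def leakage_audit(split: Split, mols: list[Molecule]) -> dict:
    """Audit a split for scaffold leakage between train and test.

    Reports the fraction of test-set scaffolds present verbatim in the
    train set, the maximum cross-set scaffold similarity, and whether the
    three sets are pairwise disjoint and cover the input.
    """
    by_id = {m.id: m for m in mols}
    sets = {name: list(getattr(split, name))
            for name in ("train", "validation", "test")}
    ids_flat = sets["train"] + sets["validation"] + sets["test"]
    disjoint = len(ids_flat) == len(set(ids_flat))
    covers_input = set(ids_flat) == set(by_id)

    train_scafs = {bemis_murcko(by_id[i]).smiles for i in sets["train"]
                   if i in by_id}
    test_scafs = {bemis_murcko(by_id[i]).smiles for i in sets["test"]
                  if i in by_id}
    overlap = test_scafs & train_scafs
    frac = len(overlap) / len(test_scafs) if test_scafs else 0.0

    train_fps = [maccs(s) for s in train_scafs]
    test_fps = [maccs(s) for s in test_scafs]
    return {
        "disjoint": disjoint,
        "covers_input": covers_input,
        "test_scaffolds_in_train_fraction": frac,
        "overlapping_scaffolds": sorted(overlap),
        "max_train_test_scaffold_tanimoto":
            _max_cross_similarity(train_fps, test_fps),
    }
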