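"""Pool/Buffer/Seed data-stream active-learning simulation.

Four disjoint example sets evolve over selection rounds:

* **Pool** — the unlabeled stream source;
* **Buffer** — the ranking window from which candidates are selected;
* **Seed** — the initial labeled training set;
* **Acquired** (the actively collected set, ``sddf`` in the state) — grows
  by the top-ranked Buffer examples each round.

Each round the committee is retrained from scratch on Seed + Acquired,
re-ranks the Buffer under the configured strategy, moves the top
``per_round_moved`` examples into the Acquired set, and refills the Buffer
with the same number of random Pool examples.  The learning curve records
test MAE per round.  Strategy comparisons are paired: every strategy sees
the identical initial partition and refill draws for a given replicate
seed, so curves differ only through selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .molkit import LabeledDataset
from .predictors import (DEFAULT_HETEROGENEOUS_CONFIGS, Ensemble,
                         GramAccumulator, build_members, evaluate,
                         homogeneous_configs)
from .samplers import fit_loss_predictors, rank_candidates

#: Strategy tags for compare_strategies: selection rule + committee kind.
STRATEGY_TAGS = ("RAND", "X5", "VAR", "LOSSFN")


@dataclass
class SimConfig:
    """Simulation sizes and components.

    Defaults are a 1:100 scaling of the platform protocol (Seed 100k,
    Buffer 60k, 30k moved per round); the refill size always equals the
    number moved, replenishing exactly what was taken.
    """

    seed_size: int = 1000
    buffer_size: int = 600
    per_round_moved: int = 300
    n_rounds: int = 5
    strategy: str = "VAR"
    member_configs: tuple = DEFAULT_HETEROGENEOUS_CONFIGS
    test_data: LabeledDataset | None = None

    refill_size: int = field(init=False)

    def __post_init__(self):
        if self.per_round_moved > self.buffer_size:
            raise ValueError("per_round_moved must not exceed buffer_size")
        self.refill_size = self.per_round_moved

    def min_data_size(self) -> int:
        return (self.seed_size + self.buffer_size
                + self.n_rounds * self.per_round_moved)


@dataclass
class SimState:
    """Evolving example sets (positions into the backing dataset)."""

    pool: list[int]
    buffer: list[int]
    seed: list[int]
    sddf: list[int]
    round: int = 0
    curve: list[dict] = field(default_factory=list)
    base_seed: int = 0
    # Incremental-training state: per-member Gram accumulators plus the
    # number of labeled positions already folded in.  Ridge training is
    # closed-form, so accumulating the new rows each round is exactly a
    # from-scratch refit on Seed + Acquired.
    accums: list | None = field(default=None, repr=False)
    n_seen: int = 0

    def assert_disjoint(self):
        sets = [set(self.pool), set(self.buffer), set(self.seed),
                set(self.sddf)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise AssertionError("Pool/Buffer/Seed/Acquired sets overlap")

    @property
    def labeled_count(self) -> int:
        return len(self.seed) + len(self.sddf)


def init_simulation(data: LabeledDataset, cfg: SimConfig, seed: int) -> SimState:
    """Draw Seed and Buffer uniformly without replacement; Pool is the rest."""
    need = cfg.min_data_size()
    if len(data) < need:
        raise ValueError(
            f"dataset too small: {len(data)} examples, need >= {need} "
            f"(seed {cfg.seed_size} + buffer {cfg.buffer_size} + "
            f"{cfg.n_rounds} x {cfg.per_round_moved})")
    rng = np.random.default_rng(int(seed) % (2**31))
    order = rng.permutation(len(data)).tolist()
    seed_set = order[:cfg.seed_size]
    buffer = order[cfg.seed_size:cfg.seed_size + cfg.buffer_size]
    pool = order[cfg.seed_size + cfg.buffer_size:]
    state = SimState(pool=pool, buffer=buffer, seed=seed_set, sddf=[],
                     base_seed=int(seed) % (2**31))
    state.assert_disjoint()
    return state


def _train_for_round(state: SimState, cfg: SimConfig, data: LabeledDataset
                     ) -> Ensemble:
    # Member seeds are fixed per replicate (not per round) so basis jitters
    # stay stable across retrains; only the training set grows.
    if state.accums is None:
        members = build_members(cfg.member_configs, seed=state.base_seed)
        state.accums = [GramAccumulator(m) for m in members]
        state.n_seen = 0
    labeled = state.seed + state.sddf   # Seed first, acquisitions appended
    new = labeled[state.n_seen:]
    if new:
        confs = [data[i] for i in new]
        energies = np.array([c.energy_kcal for c in confs])
        for acc in state.accums:
            acc.add(confs, energies)
        state.n_seen = len(labeled)
    members = [acc.solve() for acc in state.accums]
    hetero = len({repr(c) for c in cfg.member_configs}) > 1
    return Ensemble(members=members, heterogeneous=hetero)


def _record(state: SimState, cfg: SimConfig, ens: Ensemble) -> None:
    mae = evaluate(ens, cfg.test_data)["mae"] if cfg.test_data else float("nan")
    state.curve.append({"round": state.round,
                        "labeled_count": state.labeled_count,
                        "test_mae_kcal_mol": mae})


def run_round(state: SimState, cfg: SimConfig, data: LabeledDataset) -> SimState:
    """One selection round; mutates and returns the state."""
    ens = _train_for_round(state, cfg, data)
    _record(state, cfg, ens)

    buffer_confs = [data[i] for i in state.buffer]
    rank_seed = (state.base_seed * 1000003 + 977 * state.round + 13) % (2**31)
    if cfg.strategy == "LOSSFN":
        lp = fit_loss_predictors(ens, data.subset(state.seed + state.sddf))
        ranked = rank_candidates("LOSSFN", buffer_confs, seed=rank_seed, lp=lp)
    elif cfg.strategy == "RAND":
        ranked = rank_candidates("RAND", buffer_confs, seed=rank_seed)
    else:  # VAR-style committee disagreement
        ranked = rank_candidates("VAR", buffer_confs, seed=rank_seed, ens=ens)

    pos_of = {data[i].key: i for i in state.buffer}
    chosen = [pos_of[c.key] for c in ranked.top(cfg.per_round_moved)]
    chosen_set = set(chosen)
    state.sddf.extend(chosen)
    state.buffer = [i for i in state.buffer if i not in chosen_set]

    # Refill draws depend only on (replicate seed, round), keeping paired
    # strategies on identical refill streams while their selections differ.
    refill_rng = np.random.default_rng(
        (state.base_seed * 2654435761 + 31 * state.round + 7) % (2**31))
    n_refill = min(cfg.refill_size, len(state.pool))
    take = refill_rng.choice(len(state.pool), size=n_refill, replace=False)
    take_set = set(take.tolist())
    state.buffer.extend(state.pool[i] for i in sorted(take_set))
    state.pool = [p for i, p in enumerate(state.pool) if i not in take_set]

    state.round += 1
    state.assert_disjoint()
    return state


def run_simulation(data: LabeledDataset, cfg: SimConfig, seed: int) -> SimState:
    """Full simulation: n_rounds selection rounds plus the final retrain.

    The curve has ``n_rounds + 1`` points; row ``r`` is the test MAE of the
    committee trained on Seed plus the first ``r`` rounds of selections.
    """
    state = init_simulation(data, cfg, seed)
    for _ in range(cfg.n_rounds):
        run_round(state, cfg, data)
    ens = _train_for_round(state, cfg, data)
    _record(state, cfg, ens)
    return state


def _strategy_config(tag: str, cfg: SimConfig) -> SimConfig:
    tag = tag.upper()
    if tag not in STRATEGY_TAGS:
        raise ValueError(f"unknown strategy tag {tag!r}; expected {STRATEGY_TAGS}")
    if tag == "X5":
        # Homogeneous committee (one config, five seeds) ranked by
        # disagreement — the same-architecture baseline.
        return replace(cfg, strategy="VAR",
                       member_configs=homogeneous_configs(n=5))
    return replace(cfg, strategy=tag)


def compare_strategies(cfg_base: SimConfig, strategies, replicate_seeds,
                       data: LabeledDataset) -> pd.DataFrame:
    """Paired strategy comparison over replicate seeds.

    Returns a tidy frame with columns strategy, replicate_seed, round,
    labeled_count, test_mae_kcal_mol.
    """
    strategies = list(strategies)
    replicate_seeds = list(replicate_seeds)
    if len(strategies) < 2 or len(replicate_seeds) < 2:
        raise ValueError("need >= 2 strategies and >= 2 replicate seeds")
    rows = []
    for rep in replicate_seeds:
        for tag in strategies:
            cfg = _strategy_config(tag, cfg_base)
            state = run_simulation(data, cfg, seed=rep)
            for point in state.curve:
                rows.append({"strategy": tag.upper(), "replicate_seed": rep,
                             **point})
    return pd.DataFrame(rows)


def summarize_curves(table: pd.DataFrame) -> pd.DataFrame:
    """Per-strategy mean and std of test MAE per round."""
    return (table.groupby(["strategy", "round", "labeled_count"])
            ["test_mae_kcal_mol"].agg(["mean", "std"]).reset_index())
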