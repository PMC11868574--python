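"""Trainable conformational-energy predictors and the committee ensemble.

The built-in predictor is a ridge-regularized linear model over per-edge
radial-basis features of the conformation graph: every atom pair that is
bonded or closer than a distance threshold contributes a Gaussian basis
expansion of its distance into a weight block indexed by (element pair,
bonded flag), plus per-element composition terms.  Energies are therefore
sums over edges, so the analytic gradient (and hence the force, its
negation) is exact and cheap.  Closed-form training keeps full
active-learning simulations deterministic and fast on one CPU.

Committee diversity comes from two sources: heterogeneous member
configurations (different basis sizes, widths, penalties), and a seeded
random jitter of the basis-center positions that plays the role random
initialization plays for neural networks, so that same-config ensembles
with different seeds still disagree away from the training data.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.linear_model import Ridge

from .molkit import (Conformation, LabeledDataset, Molecule, ToyOracleParams,
                     toy_oracle_energy_forces)

DEFAULT_DISTANCE_THRESHOLD = 4.0  # Angstrom

# Element classes for pair-type feature blocks.  Halogens share one class
# ("G"), sulfur/phosphorus and any exotic element share another ("S"): a
# pair block's weight curve is a free function of distance, so elements
# whose pair-distance distributions occupy different ranges can share a
# block without conflict, and the smaller alphabet keeps the feature
# dimension desk-scale.
_ELEMENT_CLASSES = ["H", "C", "N", "O", "F", "X", "S"]
_ELEM_INDEX = {"H": 0, "C": 1, "N": 2, "O": 3, "F": 4,
               "Cl": 5, "Br": 5, "I": 5,
               "S": 6, "P": 6}

# Composition (linear energy-shifter) features are per true element, not per
# class: per-element reference constants in total-energy-scale labels must
# be exactly representable or they leak into the distance curves.
_COMP_ELEMENTS = ["H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "*"]
_COMP_INDEX = {s: i for i, s in enumerate(_COMP_ELEMENTS)}
_N_COMP = len(_COMP_ELEMENTS)


def _comp_index(symbol: str) -> int:
    return _COMP_INDEX.get(symbol, _COMP_INDEX["*"])
_N_ELEM = len(_ELEMENT_CLASSES)
_N_PAIR = _N_ELEM * (_N_ELEM + 1) // 2

_PAIR_BLOCK = {}
for _a in range(_N_ELEM):
    for _b in range(_a, _N_ELEM):
        _PAIR_BLOCK[(_a, _b)] = len(_PAIR_BLOCK)


def _elem_class(symbol: str) -> int:
    return _ELEM_INDEX.get(symbol, _ELEM_INDEX["S"])


# ---------------------------------------------------------------------------
# Crude physical prior for delta-learning
# ---------------------------------------------------------------------------
# Predictors learn the *residual* against a fixed, deliberately generic
# bonded + Lennard-Jones potential: single-bond equilibrium lengths with no
# bond-order correction, one spring constant for every bond, and one LJ
# parameter set per hydrogen/heavy split.  The prior is far too crude to be
# accurate, but it guarantees a repulsive wall at short range and a bond
# restoring force at large stretch, so dynamics driven by the model can
# never wander into unphysical geometries just because the training set
# carried no data there.  Delta-learning against a cheap reference is the
# standard construction for ML potentials.
_PRIOR_COVALENT_RADIUS = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}
_PRIOR_BOND_K = 200.0            # kcal/mol/A^2, generic
_PRIOR_LJ = {"H": (0.03, 2.6)}   # eps kcal/mol, sigma A; heavy atoms below
_PRIOR_LJ_HEAVY = (0.12, 3.3)

_PRIOR_CACHE: dict = {}


def _prior_params(mol: Molecule) -> ToyOracleParams:
    params = _PRIOR_CACHE.get(mol.smiles)
    if params is not None:
        return params
    symbols = mol.symbols()
    bonds = np.array(mol.bonds, dtype=int).reshape(-1, 2)
    d0 = np.array([_PRIOR_COVALENT_RADIUS.get(symbols[i], 1.0)
                   + _PRIOR_COVALENT_RADIUS.get(symbols[j], 1.0)
                   for i, j in bonds])
    n = mol.n_atoms
    adj = [set() for _ in range(n)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    excluded = {tuple(sorted(b)) for b in bonds.tolist()}
    for j in range(n):
        for i in adj[j]:
            for k in adj[j]:
                if i < k:
                    excluded.add((i, k))
    pairs = np.array([(i, j) for i in range(n) for j in range(i + 1, n)
                      if (i, j) not in excluded], dtype=int).reshape(-1, 2)
    lj = [_PRIOR_LJ.get(sym, _PRIOR_LJ_HEAVY) for sym in symbols]
    eps = np.array([np.sqrt(lj[i][0] * lj[j][0]) for i, j in pairs])
    sigma = np.array([(lj[i][1] + lj[j][1]) / 2 for i, j in pairs])
    params = ToyOracleParams(bond_idx=bonds,
                             bond_k=np.full(len(bonds), _PRIOR_BOND_K),
                             bond_d0=d0, pair_idx=pairs, pair_eps=eps,
                             pair_sigma=sigma)
    if len(_PRIOR_CACHE) > 20000:
        _PRIOR_CACHE.clear()
    _PRIOR_CACHE[mol.smiles] = params
    return params


def prior_energy_forces(mol: Molecule, coords: np.ndarray
                        ) -> tuple[float, np.ndarray]:
    """Energy and forces of the fixed crude prior potential."""
    return toy_oracle_energy_forces(coords, _prior_params(mol))


def prior_energies(confs) -> np.ndarray:
    return np.array([prior_energy_forces(c.molecule, c.coords)[0]
                     for c in confs])


@dataclass(frozen=True)
class MolGraph:
    """Conformation graph: nodes are atoms, edges are bonded-or-near pairs."""

    node_z: np.ndarray        # atomic numbers
    node_mass: np.ndarray     # amu
    node_class: np.ndarray    # element-class index (pair blocks)
    node_comp: np.ndarray     # element index (composition features)
    edge_idx: np.ndarray      # E x 2, i < j, each undirected edge once
    edge_dist: np.ndarray     # Angstrom
    edge_bonded: np.ndarray   # bool
    edge_pair: np.ndarray     # pair-type block index


def featurize(conf: Conformation,
              distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD) -> MolGraph:
    """Build the conformation graph.

    An atom pair is an edge iff it is covalently bonded (at any distance)
    or its distance is below ``distance_threshold``.
    """
    cache = getattr(conf, "_graph_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(conf, "_graph_cache", cache)
    if distance_threshold in cache:
        return cache[distance_threshold]

    mol = conf.molecule
    coords = conf.coords
    n = mol.n_atoms
    diff = coords[:, None, :] - coords[None, :, :]
    dmat = np.linalg.norm(diff, axis=-1)
    iu, ju = np.triu_indices(n, k=1)
    bonded_set = {tuple(sorted(b)) for b in mol.bonds}
    bonded = np.array([(i, j) in bonded_set for i, j in zip(iu, ju)])
    near = dmat[iu, ju] < distance_threshold
    keep = bonded | near
    ei, ej = iu[keep], ju[keep]
    classes = np.array([_elem_class(s) for s in mol.symbols()], dtype=int)
    pair = np.array([_PAIR_BLOCK[tuple(sorted((classes[i], classes[j])))]
                     for i, j in zip(ei, ej)], dtype=int)
    graph = MolGraph(
        node_z=np.array([z for _, z, _ in mol.atoms], dtype=int),
        node_mass=mol.masses(),
        node_class=classes,
        node_comp=np.array([_comp_index(s) for s in mol.symbols()],
                           dtype=int),
        edge_idx=np.stack([ei, ej], axis=1),
        edge_dist=dmat[ei, ej],
        edge_bonded=bonded[keep],
        edge_pair=pair,
    )
    cache[distance_threshold] = graph
    return graph


@dataclass(frozen=True)
class RBFConfig:
    """Hyperparameters of one RBF pair-regression committee member."""

    n_centers: int = 12
    d_min: float = 0.7
    d_max: float = DEFAULT_DISTANCE_THRESHOLD
    width_factor: float = 1.0      # width = factor * center spacing
    alpha: float = 1e-5            # ridge penalty
    use_prior: bool = True         # delta-learn on the crude physical prior
    bootstrap: bool = True         # Poisson-bootstrap example weights per
                                   # seed, the committee's second diversity
                                   # source (label-conflict sensitivity)
    curvature: float = 1e-4        # curvature (P-spline style) penalty on
                                   # each pair-block weight curve, keeping
                                   # the learned potential's gradient smooth
                                   # enough to drive dynamics
    center_jitter: float = 0.3     # seeded jitter, fraction of spacing
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD
    seed: int = 0


# Heterogeneous default committee (5 members), mirroring an ensemble of
# architecturally distinct models at desk scale.  Capacities are chosen so
# members remain data-limited at the simulation's seed size and keep
# learning as examples accumulate.
DEFAULT_HETEROGENEOUS_CONFIGS = (
    RBFConfig(n_centers=32, width_factor=1.0, alpha=1e-6),
    RBFConfig(n_centers=24, width_factor=1.3, alpha=1e-5),
    RBFConfig(n_centers=40, width_factor=0.8, alpha=1e-6),
    RBFConfig(n_centers=28, width_factor=0.9, alpha=3e-6),
    RBFConfig(n_centers=36, width_factor=1.1, alpha=1e-5),
)

#: Representative mid-committee configuration for same-config committees.
DEFAULT_HOMOGENEOUS_BASE = RBFConfig(n_centers=28, width_factor=0.9, alpha=3e-6)


def homogeneous_configs(base: RBFConfig | None = None, n: int = 5
                        ) -> tuple[RBFConfig, ...]:
    """Same-configuration committee; diversity comes from seeds alone."""
    base = base or DEFAULT_HOMOGENEOUS_BASE
    return tuple(replace(base) for _ in range(n))


# Design-row cache shared across retrains: rows depend only on the basis
# signature and the conformation geometry, both immutable.
_ROW_CACHE: dict = {}
_ROW_CACHE_LIMIT = 25000


def _conf_cache_key(conf: Conformation) -> tuple:
    return (conf.molecule.smiles, conf.conf_id,
            zlib.crc32(np.ascontiguousarray(conf.coords).tobytes()))


def _bootstrap_weights(member_seed: int, confs) -> np.ndarray:
    """Deterministic Poisson(1) weight per (member, conformation).

    Each weight depends only on the member seed and the conformation's
    identity, never on batch composition or order, so incremental Gram
    accumulation and one-shot fits produce identical models.
    """
    out = np.empty(len(confs))
    for i, conf in enumerate(confs):
        key = f"{member_seed}|{conf.molecule.smiles}|{conf.conf_id}".encode()
        sub = (zlib.crc32(key)
               ^ zlib.crc32(np.ascontiguousarray(conf.coords).tobytes()))
        out[i] = np.random.default_rng(sub % (2**31)).poisson(1.0)
    return out


class RBFPairRegressor:
    """Built-in predictor: ridge regression over per-edge RBF features."""

    def __init__(self, config: RBFConfig | None = None):
        self.config = config or RBFConfig()
        cfg = self.config
        spacing = (cfg.d_max - cfg.d_min) / max(cfg.n_centers - 1, 1)
        rng = np.random.default_rng(cfg.seed % (2**31))
        jitter = rng.uniform(-cfg.center_jitter * spacing,
                             cfg.center_jitter * spacing, size=cfg.n_centers)
        self.centers = np.linspace(cfg.d_min, cfg.d_max, cfg.n_centers) + jitter
        self.width = cfg.width_factor * spacing
        self.n_features = _N_PAIR * 2 * cfg.n_centers + _N_COMP
        self.coef_: np.ndarray | None = None
        self._sig = (zlib.crc32(self.centers.round(9).tobytes()),
                     round(self.width, 9), round(cfg.distance_threshold, 9))

    def penalty_matrix(self) -> np.ndarray:
        """Tikhonov matrix: ridge plus per-block curvature penalty.

        The curvature term integrates the squared second derivative of
        every pair-block weight curve over a dense distance grid, damping
        oscillations of the fitted potential between training distances —
        an energy-only fit leaves the gradient unconstrained otherwise.
        """
        cfg = self.config
        p = self.n_features
        pen = cfg.alpha * np.eye(p)
        if cfg.curvature > 0:
            grid = np.linspace(cfg.d_min - 0.3, cfg.d_max + 0.3,
                               4 * cfg.n_centers)
            delta = (grid[:, None] - self.centers[None, :]) / self.width
            phi = np.exp(-0.5 * delta**2)
            d2 = phi * (delta**2 - 1.0) / self.width**2
            block_pen = cfg.curvature * (d2.T @ d2) * (grid[1] - grid[0])
            for b in range(_N_PAIR * 2):
                i = b * cfg.n_centers
                pen[i:i + cfg.n_centers, i:i + cfg.n_centers] += block_pen
        return pen

    # -- features -----------------------------------------------------------

    def _phi(self, d: np.ndarray) -> np.ndarray:
        return np.exp(-((d[:, None] - self.centers[None, :]) ** 2)
                      / (2.0 * self.width**2))

    def _design_row(self, conf: Conformation, cache: bool = True) -> np.ndarray:
        key = (self._sig, *_conf_cache_key(conf)) if cache else None
        if cache:
            row = _ROW_CACHE.get(key)
            if row is not None:
                return row
        g = featurize(conf, self.config.distance_threshold)
        cfg = self.config
        row = np.zeros(self.n_features)
        if len(g.edge_idx):
            block = (g.edge_pair * 2 + g.edge_bonded.astype(int)) * cfg.n_centers
            phi = self._phi(g.edge_dist)
            cols = block[:, None] + np.arange(cfg.n_centers)[None, :]
            np.add.at(row, cols.ravel(), phi.ravel())
        comp = np.bincount(g.node_comp, minlength=_N_COMP)
        row[-_N_COMP:] = comp
        if cache:
            if len(_ROW_CACHE) > _ROW_CACHE_LIMIT:
                _ROW_CACHE.clear()
            _ROW_CACHE[key] = row
        return row

    def _design_matrix(self, confs, cache: bool = True) -> np.ndarray:
        return np.stack([self._design_row(c, cache=cache) for c in confs])

    # -- Predictor interface -------------------------------------------------

    def fit(self, data: LabeledDataset) -> "RBFPairRegressor":
        if len(data) < 2:
            raise ValueError("need at least 2 labeled examples")
        y = data.energies_kcal()
        if np.ptp(y) == 0:
            warnings.warn("degenerate training data: all energies equal; "
                          "fitting a constant model")
        X = self._design_matrix(data.entries)
        if self.config.use_prior:
            y = y - prior_energies(data.entries)
        if self.config.bootstrap:
            w = _bootstrap_weights(self.config.seed, data.entries)
            a = X.T @ (X * w[:, None]) + self.penalty_matrix()
            b = X.T @ (w * y)
        else:
            a = X.T @ X + self.penalty_matrix()
            b = X.T @ y
        try:
            self.coef_ = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            self.coef_ = np.linalg.lstsq(a, b, rcond=None)[0]
        return self

    def _check_fitted(self):
        if self.coef_ is None:
            raise RuntimeError("predictor is not trained")

    def predict_energy(self, conf: Conformation) -> float:
        self._check_fitted()
        e = float(self._design_row(conf) @ self.coef_)
        if self.config.use_prior:
            e += prior_energy_forces(conf.molecule, conf.coords)[0]
        return e

    def predict_energies(self, confs) -> np.ndarray:
        self._check_fitted()
        pred = self._design_matrix(confs) @ self.coef_
        if self.config.use_prior:
            pred = pred + prior_energies(confs)
        return pred

    def predict_forces(self, conf: Conformation) -> np.ndarray:
        """Analytic forces = -dE/dr for the current edge set."""
        self._check_fitted()
        return self.forces_for_coords(conf, conf.coords)

    def forces_for_coords(self, conf: Conformation, coords: np.ndarray
                          ) -> np.ndarray:
        e, f = self.energy_forces_for_coords(conf, coords)
        return f

    def energy_forces_for_coords(self, conf: Conformation, coords: np.ndarray,
                                 graph: MolGraph | None = None
                                 ) -> tuple[float, np.ndarray]:
        """Energy and forces at arbitrary coordinates of the same topology.

        The edge set is rebuilt at the given coordinates (bonds always kept,
        nonbonded pairs within the distance threshold) unless a prebuilt
        ``graph`` for these coordinates is supplied.
        """
        self._check_fitted()
        cfg = self.config
        if graph is None:
            probe = Conformation(conf.molecule, conf_id="__probe__",
                                 coords=coords, provenance=conf.provenance)
            graph = featurize(probe, cfg.distance_threshold)
        g = graph
        comp = np.bincount(g.node_comp, minlength=_N_COMP)
        energy = float(comp @ self.coef_[-_N_COMP:])
        forces = np.zeros_like(coords, dtype=float)
        if len(g.edge_idx):
            phi = self._phi(g.edge_dist)
            block = (g.edge_pair * 2 + g.edge_bonded.astype(int)) * cfg.n_centers
            cols = block[:, None] + np.arange(cfg.n_centers)[None, :]
            w = self.coef_[cols]                       # E x n_centers
            energy += float(np.sum(w * phi))
            dphi = phi * (-(g.edge_dist[:, None] - self.centers[None, :])
                          / self.width**2)
            de_dd = np.sum(w * dphi, axis=1)           # dE/dd per edge
            dvec = coords[g.edge_idx[:, 0]] - coords[g.edge_idx[:, 1]]
            unit = dvec / np.maximum(g.edge_dist, 1e-12)[:, None]
            grad = de_dd[:, None] * unit
            np.add.at(forces, g.edge_idx[:, 0], -grad)
            np.add.at(forces, g.edge_idx[:, 1], grad)
        if cfg.use_prior:
            e0, f0 = prior_energy_forces(conf.molecule, coords)
            energy += e0
            forces += f0
        return energy, forces

    def clone_with_seed(self, seed: int) -> "RBFPairRegressor":
        return RBFPairRegressor(replace(self.config, seed=int(seed)))


@dataclass
class Ensemble:
    """Ordered committee of >= 2 predictors; prediction is the member mean."""

    members: list
    heterogeneous: bool = True

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("ensemble needs at least 2 members")

    @property
    def n_members(self) -> int:
        return len(self.members)

    def predict_energy(self, conf: Conformation) -> float:
        return float(np.mean([m.predict_energy(conf) for m in self.members]))

    def member_energies(self, conf: Conformation) -> np.ndarray:
        return np.array([m.predict_energy(conf) for m in self.members])

    def member_energies_batch(self, confs) -> np.ndarray:
        """Members x conformations energy matrix."""
        return np.stack([m.predict_energies(confs) for m in self.members])

    def predict_forces(self, conf: Conformation) -> np.ndarray:
        return np.mean([m.predict_forces(conf) for m in self.members], axis=0)

    def _shared_graph(self, conf: Conformation, coords: np.ndarray) -> MolGraph:
        # One featurization serves all members when thresholds agree.
        thresholds = {m.config.distance_threshold for m in self.members
                      if hasattr(m, "config")}
        if len(thresholds) != 1:
            return None
        probe = Conformation(conf.molecule, conf_id="__probe__", coords=coords,
                             provenance=conf.provenance)
        return featurize(probe, thresholds.pop())

    def member_forces(self, conf: Conformation,
                      coords: np.ndarray | None = None) -> np.ndarray:
        """Per-member force arrays, M x N x 3."""
        coords = conf.coords if coords is None else coords
        graph = self._shared_graph(conf, coords)
        return np.stack([m.energy_forces_for_coords(conf, coords, graph=graph)[1]
                         for m in self.members])

    def energy_forces_for_coords(self, conf: Conformation, coords: np.ndarray
                                 ) -> tuple[float, np.ndarray]:
        graph = self._shared_graph(conf, coords)
        pairs = [m.energy_forces_for_coords(conf, coords, graph=graph)
                 for m in self.members]
        energy = float(np.mean([e for e, _ in pairs]))
        forces = np.mean([f for _, f in pairs], axis=0)
        return energy, forces

    def force_function(self, conf: Conformation):
        """Callable coords -> (mean energy, mean forces) for MD drivers."""
        return lambda coords: self.energy_forces_for_coords(conf, coords)


def build_members(members, seed: int = 0) -> list:
    """Instantiate unfitted committee members with derived seeds.

    ``members`` may be RBFConfig instances or predictors exposing
    ``clone_with_seed``.  Member seeds derive from ``seed`` and position,
    so construction is deterministic and order is stable.
    """
    out = []
    for i, m in enumerate(members):
        member_seed = (int(seed) * 9973 + 7919 * i + 1) % (2**31)
        if isinstance(m, RBFConfig):
            out.append(RBFPairRegressor(replace(m, seed=member_seed)))
        else:
            out.append(m.clone_with_seed(member_seed))
    return out


def train_ensemble(members, data: LabeledDataset, seed: int = 0,
                   heterogeneous: bool | None = None) -> Ensemble:
    """Fit every member independently on the same dataset snapshot."""
    if len(data) < 10:
        raise ValueError("need at least 10 labeled examples to train")
    configs = list(members)
    fitted = [p.fit(data) for p in build_members(configs, seed)]
    if heterogeneous is None:
        heterogeneous = len({repr(m) for m in configs}) > 1
    return Ensemble(members=fitted, heterogeneous=heterogeneous)


class GramAccumulator:
    """Incremental closed-form ridge training for one member.

    Ridge regression depends on the data only through the Gram matrix
    ``X'X`` and moment vector ``X'y``, so the committee can be "retrained
    from scratch" on a growing training set by accumulating the new rows'
    contributions and re-solving — bitwise order-independent up to
    floating-point summation, and identical to a fresh
    :meth:`RBFPairRegressor.fit` on the full set.
    """

    def __init__(self, member: RBFPairRegressor):
        self.member = member
        p = member.n_features
        self.xtx = np.zeros((p, p))
        self.xty = np.zeros(p)
        self.n = 0

    def add(self, confs, energies: np.ndarray) -> None:
        if not len(confs):
            return
        y = np.asarray(energies, dtype=float)
        if self.member.config.use_prior:
            y = y - prior_energies(confs)
        X = self.member._design_matrix(confs, cache=False)
        if self.member.config.bootstrap:
            w = _bootstrap_weights(self.member.config.seed, confs)
            self.xtx += X.T @ (X * w[:, None])
            self.xty += X.T @ (w * y)
        else:
            self.xtx += X.T @ X
            self.xty += X.T @ y
        self.n += len(confs)

    def solve(self) -> RBFPairRegressor:
        """Refresh the member's weights from the accumulated moments."""
        if self.n < 2:
            raise ValueError("need at least 2 accumulated examples")
        a = self.xtx + self.member.penalty_matrix()
        try:
            self.member.coef_ = np.linalg.solve(a, self.xty)
        except np.linalg.LinAlgError:
            self.member.coef_ = np.linalg.lstsq(a, self.xty, rcond=None)[0]
        return self.member


def save_ensemble(ens: Ensemble, path: str) -> None:
    """Write a self-describing JSON checkpoint (configs + weight arrays)."""
    import dataclasses
    import json
    payload = {"format": "confactory-ensemble-v1",
               "heterogeneous": ens.heterogeneous, "members": []}
    for m in ens.members:
        if not isinstance(m, RBFPairRegressor):
            raise TypeError("only RBFPairRegressor members are serializable")
        m._check_fitted()
        payload["members"].append({
            "config": dataclasses.asdict(m.config),
            "coef": m.coef_.tolist(),
        })
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_ensemble(path: str) -> Ensemble:
    import json
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "confactory-ensemble-v1":
        raise ValueError(f"not an ensemble checkpoint: {path}")
    members = []
    for entry in payload["members"]:
        member = RBFPairRegressor(RBFConfig(**entry["config"]))
        member.coef_ = np.array(entry["coef"], dtype=float)
        members.append(member)
    return Ensemble(members=members,
                    heterogeneous=bool(payload["heterogeneous"]))


def ensemble_predict(ens: Ensemble, conf: Conformation
                     ) -> tuple[float, np.ndarray]:
    """(mean energy, per-member energies in member order)."""
    per_member = ens.member_energies(conf)
    return float(per_member.mean()), per_member


def disagreement_rsd(per_member: np.ndarray, eps: float = 1e-8) -> float:
    """Relative standard deviation of committee predictions.

    Population standard deviation divided by ``max(|mean|, eps)``; the
    epsilon guard keeps the score finite when the mean crosses zero.
    """
    values = np.asarray(per_member, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 member predictions")
    return float(values.std() / max(abs(values.mean()), eps))


def evaluate(model, data: LabeledDataset) -> dict:
    """Per-conformation MAE and RMSE (kcal/mol) of a predictor or ensemble."""
    if len(data) == 0:
        raise ValueError("empty evaluation data")
    y = data.energies_kcal()
    if isinstance(model, Ensemble):
        pred = model.member_energies_batch(data.entries).mean(axis=0)
    elif hasattr(model, "predict_energies"):
        pred = model.predict_energies(data.entries)
    else:
        pred = np.array([model.predict_energy(c) for c in data.entries])
    err = pred - y
    return {"mae": float(np.mean(np.abs(err))),
            "rmse": float(np.sqrt(np.mean(err**2)))}
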