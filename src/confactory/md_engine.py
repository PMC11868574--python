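"""Langevin molecular dynamics driven by predicted forces.

The integrator is BAOAB splitting (velocity Verlet in the zero-friction,
zero-temperature limit) with Maxwell-Boltzmann velocity initialization.
Units: coordinates A, time fs, masses amu, energies kcal/mol, forces
kcal/mol/A; the instantaneous temperature uses ``T = 2 KE / (k_B 3N)``
with no removal of rigid-body degrees of freedom.

A committee confidence score judges each saved frame: for every atom, the
cosine of the angle between each pair of members' force vectors on that
atom is computed, the minimum over member pairs is taken, and the score is
the mean of these atomwise minima.  Frames where the committee's forces
point in conflicting directions score low and are the ones worth labeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .molkit import Conformation
from .predictors import Ensemble
from .units import ACCEL_KCAL_PER_AMU_A, KB_KCAL_MOL_K, KE_AMU_A2_FS2_TO_KCAL

DEFAULT_TEMP_CAP_K = 600.0


@dataclass
class MDConfig:
    """Langevin integration settings."""

    timestep_fs: float = 1.0
    n_steps: int = 1000
    save_stride: int = 10
    friction_ps: float = 1.0          # friction coefficient, ps^-1
    temperature_K: float = 300.0      # bath temperature
    temp_cap_K: float = DEFAULT_TEMP_CAP_K
    seed: int = 0

    def __post_init__(self):
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        if self.save_stride < 1:
            raise ValueError("save_stride must be >= 1")

    @classmethod
    def training_mode(cls, seed: int = 0) -> "MDConfig":
        """Long trajectories for data generation: 1 ps, every 10th frame."""
        return cls(n_steps=1000, save_stride=10, seed=seed)

    @classmethod
    def test_mode(cls, seed: int = 0) -> "MDConfig":
        """Short evaluation runs: 0.1 ps, every frame saved, 600 K cap."""
        return cls(n_steps=100, save_stride=1, temp_cap_K=600.0, seed=seed)


@dataclass
class Frame:
    step: int
    coords: np.ndarray
    velocities: np.ndarray            # A/fs
    temperature_K: float
    energy_kcal: float
    over_cap: bool = False            # the frame that tripped the cap
    zero_force_atoms: int = 0         # diagnostics for confidence scoring


@dataclass
class Trajectory:
    source: Conformation
    frames: list[Frame] = field(default_factory=list)
    termination: str = "completed"    # or "temperature_cap"

    def __len__(self):
        return len(self.frames)

    def frame_conformation(self, frame: Frame, tag: str = "md") -> Conformation:
        return Conformation(self.source.molecule,
                            conf_id=f"{self.source.conf_id}-{tag}{frame.step}",
                            coords=frame.coords.copy(), provenance="md")


def confidence_score(force_set: np.ndarray) -> float:
    """Committee force-agreement score in [-1, 1].

    ``force_set`` is M x N x 3 (members x atoms x xyz).  Per atom, the
    minimum pairwise cosine similarity between member force vectors is
    taken; the score is the mean over atoms.  A zero force vector has no
    direction, so its cosine with anything is defined as 0.
    """
    fs = np.asarray(force_set, dtype=float)
    if fs.ndim != 3 or fs.shape[2] != 3:
        raise ValueError("force set must be M x N x 3")
    m = fs.shape[0]
    if m < 2:
        raise ValueError("confidence score needs at least 2 members")
    norms = np.linalg.norm(fs, axis=2)                      # M x N
    safe = np.where(norms > 0, norms, 1.0)
    units = fs / safe[:, :, None]
    cos = np.einsum("qnd,knd->qkn", units, units)           # M x M x N
    nonzero = norms > 0
    valid = nonzero[:, None, :] & nonzero[None, :, :]
    cos = np.where(valid, cos, 0.0)
    qi, ki = np.triu_indices(m, k=1)
    per_atom_min = cos[qi, ki, :].min(axis=0)               # N
    return float(per_atom_min.mean())


def instantaneous_temperature(velocities: np.ndarray, masses: np.ndarray
                              ) -> float:
    """Kinetic temperature in K with N_dof = 3N."""
    v = np.asarray(velocities, dtype=float)
    m = np.asarray(masses, dtype=float)
    if v.shape[0] != m.shape[0]:
        raise ValueError("velocity and mass shapes do not match")
    ke = 0.5 * float(np.sum(m[:, None] * v**2)) * KE_AMU_A2_FS2_TO_KCAL
    n_dof = 3 * v.shape[0]
    return 2.0 * ke / (KB_KCAL_MOL_K * n_dof)


def maxwell_boltzmann_velocities(masses: np.ndarray, temperature_K: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Per-component Gaussian velocities at the bath temperature (A/fs)."""
    sigma = np.sqrt(KB_KCAL_MOL_K * max(temperature_K, 0.0)
                    * ACCEL_KCAL_PER_AMU_A / masses)
    return rng.normal(size=(len(masses), 3)) * sigma[:, None]


def run_md(conf: Conformation, force_fn, cfg: MDConfig) -> Trajectory:
    """Integrate Langevin dynamics from a conformation.

    ``force_fn`` maps coordinates (N x 3) to ``(energy kcal/mol, forces
    N x 3 kcal/mol/A)``; pass ``Ensemble.force_function(conf)`` to drive
    the dynamics with the committee's mean-energy gradient, or any other
    callable (e.g. the toy oracle) for reference dynamics.  The run stops
    early with termination reason ``temperature_cap`` as soon as the
    instantaneous temperature exceeds ``cfg.temp_cap_K``.
    """
    if isinstance(force_fn, Ensemble):
        force_fn = force_fn.force_function(conf)
    masses = conf.molecule.masses()
    dt = cfg.timestep_fs
    gamma = cfg.friction_ps * 1e-3                      # fs^-1
    c1 = np.exp(-gamma * dt)
    sigma_v = np.sqrt(KB_KCAL_MOL_K * max(cfg.temperature_K, 0.0)
                      * ACCEL_KCAL_PER_AMU_A / masses)
    c2 = np.sqrt(max(1.0 - c1 * c1, 0.0)) * sigma_v[:, None]

    rng = np.random.default_rng(int(cfg.seed) % (2**31))
    x = conf.coords.copy()
    v = maxwell_boltzmann_velocities(masses, cfg.temperature_K, rng)

    energy, forces = force_fn(x)
    if not np.all(np.isfinite(forces)):
        raise ValueError("non-finite force at step 0")
    accel = forces * ACCEL_KCAL_PER_AMU_A / masses[:, None]

    traj = Trajectory(source=conf)

    def _save(step, over_cap=False):
        traj.frames.append(Frame(
            step=step, coords=x.copy(), velocities=v.copy(),
            temperature_K=instantaneous_temperature(v, masses),
            energy_kcal=float(energy), over_cap=over_cap))

    _save(0)
    for step in range(1, cfg.n_steps + 1):
        v = v + 0.5 * dt * accel                        # B
        x = x + 0.5 * dt * v                            # A
        v = c1 * v + c2 * rng.normal(size=v.shape)      # O
        x = x + 0.5 * dt * v                            # A
        energy, forces = force_fn(x)
        if not np.all(np.isfinite(forces)):
            raise ValueError(f"non-finite force at step {step}")
        accel = forces * ACCEL_KCAL_PER_AMU_A / masses[:, None]
        v = v + 0.5 * dt * accel                        # B

        temp = instantaneous_temperature(v, masses)
        at_stride = step % cfg.save_stride == 0
        over_cap = temp > cfg.temp_cap_K
        if at_stride or over_cap or step == cfg.n_steps:
            _save(step, over_cap=over_cap)
        if over_cap:
            traj.termination = "temperature_cap"
            break
    return traj


def frame_confidences(traj: Trajectory, ens: Ensemble) -> np.ndarray:
    """Committee confidence score of every saved frame."""
    scores = np.empty(len(traj.frames))
    for i, frame in enumerate(traj.frames):
        forces = ens.member_forces(traj.source, frame.coords)
        zero = int(np.sum(np.linalg.norm(forces, axis=2) == 0))
        frame.zero_force_atoms = zero
        scores[i] = confidence_score(forces)
    return scores


def select_low_confidence(traj: Trajectory, ens: Ensemble, max_k: int = 6
                          ) -> list[Conformation]:
    """The (at most) ``max_k`` lowest-confidence frames as new conformations.

    Returned ascending by score; ties keep frame order.  Provenance is
    ``md``, mirroring the MD stratum of the dataset.
    """
    if not traj.frames:
        raise ValueError("empty trajectory")
    eligible = [i for i, f in enumerate(traj.frames) if not f.over_cap]
    if not eligible:
        return []
    scores = frame_confidences(traj, ens)
    order = sorted(eligible, key=lambda i: (scores[i], i))[:max_k]
    return [traj.frame_conformation(traj.frames[i]) for i in order]


def select_random_frames(traj: Trajectory, k: int, seed: int = 0
                         ) -> list[Conformation]:
    """Uniformly random saved frames — the control arm for MD sampling."""
    rng = np.random.default_rng(int(seed) % (2**31))
    eligible = [i for i, f in enumerate(traj.frames) if not f.over_cap]
    k = min(k, len(eligible))
    if k == 0:
        return []
    pick = rng.choice(len(eligible), size=k, replace=False)
    return [traj.frame_conformation(traj.frames[eligible[i]], tag="mdr")
            for i in sorted(pick.tolist())]


def evaluate_minimization(pairs, oracle_fn, ens: Ensemble) -> dict:
    """Energy-minimization metrics over (initial, final) conformation pairs.

    * ``spearman`` — rank correlation between predicted energy differences
      ``E_ens(final) - E_ens(initial)`` and the true differences;
    * ``success_rate`` — percentage of pairs whose true energy decreased;
    * ``mean_delta`` — mean true energy difference (kcal/mol).

    ``oracle_fn(conf) -> energy`` supplies ground-truth labels.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for rank correlation")
    pred_diff, true_diff = [], []
    for initial, final in pairs:
        pred_diff.append(ens.predict_energy(final) - ens.predict_energy(initial))
        true_diff.append(oracle_fn(final) - oracle_fn(initial))
    pred_diff = np.array(pred_diff)
    true_diff = np.array(true_diff)
    rho = spearmanr(pred_diff, true_diff).statistic
    return {
        "spearman": float(rho),
        "success_rate": 100.0 * float(np.mean(true_diff < 0)),
        "mean_delta": float(true_diff.mean()),
        "n_pairs": len(pairs),
    }


def write_trajectory_xyz(traj: Trajectory, path: str) -> None:
    """Multi-frame XYZ with per-frame 'step=<i> T=<K> E=<kcal/mol>' comments."""
    symbols = traj.source.molecule.symbols()
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"{len(symbols)}\n")
            fh.write(f"step={frame.step} T={frame.temperature_K:.2f} "
                     f"E={frame.energy_kcal:.6f}\n")
            for sym, (xx, yy, zz) in zip(symbols, frame.coords):
                fh.write(f"{sym} {xx:.6f} {yy:.6f} {zz:.6f}\n")
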