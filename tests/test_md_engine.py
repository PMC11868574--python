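import numpy as np
import pytest

import confactory as cf
from confactory.md_engine import (MDConfig, frame_confidences,
                                  maxwell_boltzmann_velocities, run_md)
from confactory.molkit import ToyOracleParams, toy_oracle_energy_forces
from confactory.units import KB_KCAL_MOL_K, KE_AMU_A2_FS2_TO_KCAL


def naive_confidence(force_set):
    """Reference double-loop implementation of the committee score."""
    fs = np.asarray(force_set, dtype=float)
    m, n, _ = fs.shape
    per_atom = []
    for i in range(n):
        minimum = np.inf
        for q in range(m):
            for k in range(m):
                if q == k:
                    continue
                a, b = fs[q, i], fs[k, i]
                na, nb = np.linalg.norm(a), np.linalg.norm(b)
                cos = 0.0 if na == 0 or nb == 0 else float(a @ b / (na * nb))
                minimum = min(minimum, cos)
        per_atom.append(minimum)
    return float(np.mean(per_atom))


def _diatomic(symbol="S", mass=32.06, z=16):
    return cf.Molecule(id=f"{symbol}2", smiles=f"[{symbol}][{symbol}]",
                       atoms=((symbol, z, mass), (symbol, z, mass)),
                       bonds=((0, 1),))


class TestConfidenceScore:
    def test_identical_forces_score_one(self):
        fs = np.tile(np.array([[[1.0, 2.0, 3.0]]]), (3, 1, 1))
        assert cf.confidence_score(fs) == pytest.approx(1.0)

    def test_opposite_forces_score_minus_one(self):
        fs = np.array([[[1.0, 0, 0]], [[-1.0, 0, 0]]])
        assert cf.confidence_score(fs) == pytest.approx(-1.0)

    def test_three_member_hand_case(self):
        # pairwise cosines {0, 1/sqrt(2), 1/sqrt(2)}; min 0; one atom
        s = 1 / np.sqrt(2)
        fs = np.array([[[1.0, 0, 0]], [[0.0, 1, 0]], [[s, s, 0]]])
        assert cf.confidence_score(fs) == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_reference_on_random_sets(self, rng):
        for _ in range(100):
            m = rng.integers(2, 6)
            n = rng.integers(1, 8)
            fs = rng.normal(size=(m, n, 3))
            if rng.random() < 0.3:  # exercise the zero-force convention
                fs[rng.integers(m), rng.integers(n)] = 0.0
            assert cf.confidence_score(fs) == pytest.approx(
                naive_confidence(fs), abs=1e-12)

    def test_rotation_and_member_rescale_invariance(self, rng):
        fs = rng.normal(size=(4, 6, 3))
        base = cf.confidence_score(fs)
        theta = 0.77
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        rotated = fs @ rot.T
        assert cf.confidence_score(rotated) == pytest.approx(base, abs=1e-10)
        scaled = fs.copy()
        scaled[2] *= 7.3
        assert cf.confidence_score(scaled) == pytest.approx(base, abs=1e-10)

    def test_single_member_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cf.confidence_score(np.ones((1, 3, 3)))


class TestInstantaneousTemperature:
    def test_zero_velocities(self):
        assert cf.instantaneous_temperature(np.zeros((4, 3)),
                                            np.ones(4)) == 0.0

    def test_kinetic_scaling(self, rng):
        v = rng.normal(size=(5, 3))
        m = np.ones(5) * 12.0
        t1 = cf.instantaneous_temperature(v, m)
        assert cf.instantaneous_temperature(2 * v, m) == pytest.approx(4 * t1)

    def test_argon_at_300K(self):
        m = np.array([39.948])
        speed = np.sqrt(3 * KB_KCAL_MOL_K * 300.0
                        / (m[0] * KE_AMU_A2_FS2_TO_KCAL))
        assert cf.instantaneous_temperature(
            np.array([[speed, 0, 0]]), m) == pytest.approx(300.0)

    def test_maxwell_boltzmann_equipartition(self, rng):
        masses = np.full(2000, 12.0)
        v = maxwell_boltzmann_velocities(masses, 300.0, rng)
        assert cf.instantaneous_temperature(v, masses) == pytest.approx(
            300.0, rel=0.05)


class TestRunMd:
    def _oscillator(self):
        mol = _diatomic()
        params = ToyOracleParams.for_molecule(mol, k=300.0)
        conf = cf.Conformation(
            mol, "c0", np.array([[0.0, 0, 0], [params.bond_d0[0] + 0.1, 0, 0]]))
        return conf, params

    def test_zero_friction_conserves_energy(self):
        conf, params = self._oscillator()
        cfg = MDConfig(timestep_fs=1.0, n_steps=100, save_stride=1,
                       friction_ps=0.0, temperature_K=0.0, temp_cap_K=1e9,
                       seed=1)
        traj = run_md(conf, lambda x: toy_oracle_energy_forces(x, params), cfg)
        masses = conf.molecule.masses()
        total = [f.energy_kcal
                 + 0.5 * np.sum(masses[:, None] * f.velocities**2)
                 * KE_AMU_A2_FS2_TO_KCAL for f in traj.frames]
        drift = (max(total) - min(total)) / abs(total[0])
        assert drift < 0.01
        assert traj.termination == "completed"

    def test_zero_cap_halts_at_first_step(self):
        conf, params = self._oscillator()
        cfg = MDConfig(n_steps=100, save_stride=10, temperature_K=300.0,
                       temp_cap_K=0.0, seed=2)
        traj = run_md(conf, lambda x: toy_oracle_energy_forces(x, params), cfg)
        assert traj.termination == "temperature_cap"
        assert traj.frames[-1].step == 1
        assert traj.frames[-1].over_cap

    def test_deterministic_for_fixed_seed(self, small_dataset):
        conf = small_dataset[0]
        params = ToyOracleParams.for_molecule(conf.molecule)
        cfg = MDConfig(n_steps=40, save_stride=5, seed=11, temp_cap_K=1e6)
        f = lambda x: toy_oracle_energy_forces(x, params)
        a, b = run_md(conf, f, cfg), run_md(conf, f, cfg)
        assert len(a) == len(b)
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa.coords, fb.coords)

    def test_frame_steps_follow_stride(self, small_dataset):
        conf = small_dataset[1]
        params = ToyOracleParams.for_molecule(conf.molecule)
        cfg = MDConfig(n_steps=40, save_stride=7, seed=3, temp_cap_K=1e6)
        traj = run_md(conf, lambda x: toy_oracle_energy_forces(x, params), cfg)
        steps = [f.step for f in traj.frames]
        assert steps[0] == 0
        assert all(s % 7 == 0 for s in steps[:-1])
        assert steps[-1] == 40


@pytest.fixture(scope="module")
def scored_traj(small_dataset):
    conf = small_dataset[2]
    params = ToyOracleParams.for_molecule(conf.molecule)
    cfg = MDConfig(n_steps=30, save_stride=10, seed=5, temp_cap_K=1e6)
    return run_md(conf, lambda x: toy_oracle_energy_forces(x, params), cfg)


class TestFrameSelection:
    def test_few_frames_all_returned_ascending(self, scored_traj,
                                               trained_ensemble):
        selected = cf.select_low_confidence(scored_traj, trained_ensemble,
                                            max_k=6)
        assert len(selected) == len(scored_traj.frames)
        scores = frame_confidences(scored_traj, trained_ensemble)
        assert list(np.sort(scores)) == pytest.approx(
            sorted(scores[np.argsort(scores, kind="stable")]))
        assert all(c.provenance == "md" for c in selected)

    def test_lowest_k_selected(self, scored_traj, trained_ensemble):
        scores = frame_confidences(scored_traj, trained_ensemble)
        selected = cf.select_low_confidence(scored_traj, trained_ensemble,
                                            max_k=2)
        expect = np.argsort(scores, kind="stable")[:2]
        expected_ids = [scored_traj.frames[i].step for i in expect]
        got = [int(c.conf_id.rsplit("md", 1)[1]) for c in selected]
        assert got == expected_ids

    def test_random_frames_deterministic(self, scored_traj):
        a = cf.select_random_frames(scored_traj, k=2, seed=4)
        b = cf.select_random_frames(scored_traj, k=2, seed=4)
        assert [c.conf_id for c in a] == [c.conf_id for c in b]


class TestEvaluateMinimization:
    def _pairs(self, small_dataset, deltas):
        pairs, truths = [], {}
        for i, d in enumerate(deltas):
            a = small_dataset[i]
            b = cf.Conformation(a.molecule, f"{a.conf_id}-f", a.coords, "md")
            truths[a.key] = 10.0
            truths[b.key] = 10.0 + d
            pairs.append((a, b))
        return pairs, lambda c: truths[c.key]

    class _MonotonePredictor:
        def __init__(self, oracle, gain):
            self.oracle, self.gain = oracle, gain

        def predict_energy(self, conf):
            return self.gain * self.oracle(conf)

    def test_monotone_predictions_perfect_spearman(self, small_dataset):
        pairs, oracle = self._pairs(small_dataset, [-2.0, 1.0, 4.0, -0.5])
        ens = self._MonotonePredictor(oracle, gain=3.0)
        res = cf.evaluate_minimization(pairs, oracle, ens)
        assert res["spearman"] == pytest.approx(1.0)

    def test_hand_counted_success_and_delta(self, small_dataset):
        pairs, oracle = self._pairs(small_dataset, [-1.0, 1.0, 3.0])
        ens = self._MonotonePredictor(oracle, gain=1.0)
        res = cf.evaluate_minimization(pairs, oracle, ens)
        assert res["success_rate"] == pytest.approx(100 / 3, abs=0.01)
        assert res["mean_delta"] == pytest.approx(1.0)

    def test_all_minimized_full_success(self, small_dataset):
        pairs, oracle = self._pairs(small_dataset, [-1.0, -2.0, -0.1])
        ens = self._MonotonePredictor(oracle, gain=1.0)
        assert cf.evaluate_minimization(pairs, oracle, ens)[
            "success_rate"] == 100.0

    def test_too_few_pairs_rejected(self, small_dataset):
        pairs, oracle = self._pairs(small_dataset, [-1.0, 1.0])
        with pytest.raises(ValueError, match="at least 3"):
            cf.evaluate_minimization(pairs, oracle,
                                     self._MonotonePredictor(oracle, 1.0))


def test_trajectory_xyz_export(small_dataset, tmp_path):
    conf = small_dataset[0]
    params = ToyOracleParams.for_molecule(conf.molecule)
    cfg = MDConfig(n_steps=20, save_stride=10, seed=3, temp_cap_K=1e6)
    traj = run_md(conf, lambda x: toy_oracle_energy_forces(x, params), cfg)
    path = tmp_path / "traj.xyz"
    cf.write_trajectory_xyz(traj, str(path))
    lines = path.read_text().splitlines()
    n = conf.molecule.n_atoms
    assert len(lines) == len(traj.frames) * (n + 2)
    assert lines[1].startswith("step=0 T=")
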