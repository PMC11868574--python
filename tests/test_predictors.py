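import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import confactory as cf
from confactory.predictors import (GramAccumulator, RBFConfig,
                                   RBFPairRegressor, build_members,
                                   load_ensemble, save_ensemble)


def _two_atom_conf(d, bonded):
    bonds = ((0, 1),) if bonded else ()
    mol = cf.Molecule(id=f"pair-{bonded}-{d}", smiles="[C][C]",
                      atoms=(("C", 6, 12.011), ("C", 6, 12.011)), bonds=bonds)
    return cf.Conformation(mol, "c0", np.array([[0., 0, 0], [d, 0, 0]]))


class TestFeaturize:
    @pytest.mark.parametrize("d,bonded,expect_edge", [
        (5.0, True, True),    # bond overrides distance threshold
        (3.0, False, True),   # within threshold
        (5.0, False, False),  # beyond threshold, no bond
    ])
    def test_edge_rule(self, d, bonded, expect_edge):
        g = cf.featurize(_two_atom_conf(d, bonded), distance_threshold=4.0)
        assert (len(g.edge_idx) == 1) == expect_edge

    def test_edges_carry_distances_and_flags(self, small_dataset):
        conf = small_dataset[0]
        g = cf.featurize(conf)
        i, j = g.edge_idx[0]
        assert g.edge_dist[0] == pytest.approx(
            np.linalg.norm(conf.coords[i] - conf.coords[j]))
        bonded = {tuple(sorted(b)) for b in conf.molecule.bonds}
        assert all(((int(a), int(b)) in bonded) == flag
                   for (a, b), flag in zip(g.edge_idx, g.edge_bonded))


class TestTraining:
    def test_members_beat_mean_baseline(self, small_dataset, trained_ensemble):
        baseline = np.abs(small_dataset.energies_kcal()
                          - small_dataset.energies_kcal().mean()).mean()
        for member in trained_ensemble.members:
            assert cf.evaluate(member, small_dataset)["mae"] < baseline

    def test_homogeneous_clone_construction(self):
        configs = cf.homogeneous_configs(n=5)
        members = build_members(configs, seed=4)
        assert len({m.config.seed for m in members}) == 5
        assert len({m.config.n_centers for m in members}) == 1
        # different seeds jitter the basis centers differently
        assert not np.allclose(members[0].centers, members[1].centers)

    def test_retrain_on_superset_keeps_member_order(self, small_dataset):
        half = small_dataset.subset(range(0, len(small_dataset), 2))
        e1 = cf.train_ensemble(cf.DEFAULT_HETEROGENEOUS_CONFIGS, half, seed=3)
        e2 = cf.train_ensemble(cf.DEFAULT_HETEROGENEOUS_CONFIGS,
                               small_dataset, seed=3)
        assert e2.n_members == e1.n_members
        for m1, m2 in zip(e1.members, e2.members):
            assert m1.config == m2.config

    def test_degenerate_data_warns(self, small_dataset):
        flat = cf.LabeledDataset([c.with_energy(5.0)
                                  for c in small_dataset.entries[:20]])
        with pytest.warns(UserWarning, match="degenerate"):
            RBFPairRegressor(RBFConfig()).fit(flat)

    def test_training_deterministic(self, small_dataset):
        a = RBFPairRegressor(RBFConfig(seed=5)).fit(small_dataset)
        b = RBFPairRegressor(RBFConfig(seed=5)).fit(small_dataset)
        np.testing.assert_array_equal(a.coef_, b.coef_)

    def test_gram_accumulation_equals_fresh_fit(self, small_dataset):
        """Incremental Gram training is a from-scratch fit, order included."""
        member = RBFPairRegressor(RBFConfig(n_centers=16, seed=2))
        acc = GramAccumulator(member)
        half = len(small_dataset) // 2
        entries = small_dataset.entries
        y = small_dataset.energies_kcal()
        acc.add(entries[:half], y[:half])
        acc.add(entries[half:], y[half:])
        incremental = acc.solve()
        fresh = RBFPairRegressor(RBFConfig(n_centers=16, seed=2)).fit(
            small_dataset)
        pred_i = incremental.predict_energies(entries[:30])
        pred_f = fresh.predict_energies(entries[:30])
        np.testing.assert_allclose(pred_i, pred_f, rtol=1e-6, atol=1e-6)


class TestForces:
    @pytest.mark.parametrize("member_idx", [0, 2, 4])
    def test_forces_match_finite_differences(self, trained_ensemble,
                                             small_dataset, member_idx):
        member = trained_ensemble.members[member_idx]
        conf = small_dataset[5]
        _, forces = member.energy_forces_for_coords(conf, conf.coords)
        rng = np.random.default_rng(member_idx)
        h = 1e-6
        for _ in range(5):
            i = rng.integers(conf.coords.shape[0])
            d = rng.integers(3)
            cp, cm = conf.coords.copy(), conf.coords.copy()
            cp[i, d] += h
            cm[i, d] -= h
            num = -(member.energy_forces_for_coords(conf, cp)[0]
                    - member.energy_forces_for_coords(conf, cm)[0]) / (2 * h)
            assert abs(num - forces[i, d]) <= 1e-3 * max(
                1.0, np.abs(forces).max())


class TestEnsemble:
    def test_mean_of_members(self, trained_ensemble, small_dataset):
        conf = small_dataset[3]
        mean, per_member = cf.ensemble_predict(trained_ensemble, conf)
        assert len(per_member) == trained_ensemble.n_members
        assert mean == pytest.approx(per_member.mean())

    def test_member_permutation_keeps_mean(self, trained_ensemble,
                                           small_dataset):
        conf = small_dataset[4]
        reordered = cf.Ensemble(members=trained_ensemble.members[::-1])
        assert reordered.predict_energy(conf) == pytest.approx(
            trained_ensemble.predict_energy(conf))

    def test_needs_two_members(self, trained_ensemble):
        with pytest.raises(ValueError, match="at least 2"):
            cf.Ensemble(members=trained_ensemble.members[:1])

    def test_untrained_member_rejected(self, small_dataset):
        ens = cf.Ensemble(members=[RBFPairRegressor(RBFConfig()),
                                   RBFPairRegressor(RBFConfig(seed=1))])
        with pytest.raises(RuntimeError, match="not trained"):
            ens.predict_energy(small_dataset[0])

    def test_checkpoint_round_trip(self, trained_ensemble, small_dataset,
                                   tmp_path):
        path = tmp_path / "ens.ckpt"
        save_ensemble(trained_ensemble, str(path))
        back = load_ensemble(str(path))
        conf = small_dataset[7]
        assert back.predict_energy(conf) == pytest.approx(
            trained_ensemble.predict_energy(conf), rel=1e-12)


class TestDisagreementRsd:
    def test_identical_predictions_zero(self):
        assert cf.disagreement_rsd([5.0, 5.0, 5.0]) == 0.0

    def test_hand_computed_value(self):
        # population std sqrt(2/3) over mean 2
        assert cf.disagreement_rsd([1.0, 2.0, 3.0]) == pytest.approx(
            0.40825, abs=1e-5)

    def test_zero_mean_guarded(self):
        score = cf.disagreement_rsd([-1.0, 1.0])
        assert np.isfinite(score)
        assert score == pytest.approx(1.0 / 1e-8)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            cf.disagreement_rsd([1.0])

    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=2,
                    max_size=8),
           st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariant_and_scale_free(self, values, c):
        base = cf.disagreement_rsd(values)
        assert cf.disagreement_rsd(values[::-1]) == pytest.approx(
            base, rel=1e-9, abs=1e-12)
        mean = float(np.mean(values))
        if abs(mean) > 1e-3:  # away from the epsilon guard
            scaled = cf.disagreement_rsd([c * v for v in values])
            assert scaled == pytest.approx(base, rel=1e-6, abs=1e-9)


class TestEvaluate:
    def test_perfect_and_offset_predictions(self, small_dataset):
        class Fixed:
            def __init__(self, offset):
                self.offset = offset

            def predict_energy(self, conf):
                return conf.energy_kcal + self.offset

        assert cf.evaluate(Fixed(0.0), small_dataset) == {
            "mae": 0.0, "rmse": 0.0}
        res = cf.evaluate(Fixed(1.0), small_dataset)
        assert res["mae"] == pytest.approx(1.0)
        assert res["rmse"] == pytest.approx(1.0)

    def test_error_vector_0_3(self, small_dataset):
        errors = [0.0, 3.0]

        class TwoErr:
            def __init__(self):
                self.i = 0

            def predict_energy(self, conf):
                e = conf.energy_kcal + errors[self.i % 2]
                self.i += 1
                return e

        two = cf.LabeledDataset(small_dataset.entries[:2])
        res = cf.evaluate(TwoErr(), two)
        assert res["mae"] == pytest.approx(1.5)
        assert res["rmse"] == pytest.approx(2.1213, abs=1e-4)

    def test_empty_data_rejected(self, trained_ensemble):
        with pytest.raises(ValueError, match="empty"):
            cf.evaluate(trained_ensemble, cf.LabeledDataset())

    def test_ensemble_usually_no_worse_than_worst_member(self, benchmark):
        """Mean combination beats the worst committee member reliably."""
        rng = np.random.default_rng(0)
        better = 0
        trials = 10
        for t in range(trials):
            pos = rng.choice(len(benchmark.train), 300, replace=False)
            sub = benchmark.train.subset(pos.tolist())
            ens = cf.train_ensemble(cf.DEFAULT_HETEROGENEOUS_CONFIGS, sub,
                                    seed=t)
            eval_data = benchmark.held_out_eval(n=200, seed=t)
            ens_mae = cf.evaluate(ens, eval_data)["mae"]
            worst = max(cf.evaluate(m, eval_data)["mae"]
                        for m in ens.members)
            better += ens_mae <= worst
        assert better >= 0.9 * trials
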