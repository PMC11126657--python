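import numpy as np
import pytest
from scipy import stats

import wetdyn as w
from wetdyn.transition_mlp import MlpConfig, SubModel, sample_training_pixels, train_mlp

FAST = MlpConfig(iterations=1500, seed=0)


@pytest.fixture(scope="module")
def strong_signal():
    """Series where one driver strongly controls the water->salt transition."""
    cfg = w.default_config(
        seed=21,
        grid=w.GridSpec(120, 120, 30.0),
        true_P=np.array(
            [
                [0.95, 0.01, 0.02, 0.01, 0.01],
                [0.01, 0.75, 0.04, 0.02, 0.18],
                [0.02, 0.01, 0.94, 0.02, 0.01],
                [0.02, 0.01, 0.02, 0.94, 0.01],
                [0.01, 0.01, 0.02, 0.01, 0.95],
            ]
        ),
        initial_fractions=np.full(5, 0.2),
        driver_effects={(2, 5): {"dist_river": 4.0, "dem": -2.0}},
    )
    drivers = w.generate_drivers(cfg)
    maps, truth = w.generate_series(cfg, drivers)
    return cfg, drivers, maps, truth


class TestSampling:
    def test_bookkeeping_and_split(self, strong_signal):
        _, drivers, maps, _ = strong_signal
        sm = SubModel(transitions=((2, 5), (2, 3)), driver_names=tuple(sorted(drivers)))
        ts = sample_training_pixels(sm, maps[0], maps[1], drivers, n_per_class=100, seed=3)
        n = len(ts.y_train) + len(ts.y_valid)
        assert n <= 100 * (2 + 1)  # two transitions + persistence of class 2
        assert abs(len(ts.y_train) - len(ts.y_valid)) <= 1
        assert set(ts.output_labels) == {"2->5", "2->3", "persist_2"}

    def test_fixed_seed_reproducible(self, strong_signal):
        _, drivers, maps, _ = strong_signal
        sm = SubModel(transitions=((2, 5),), driver_names=tuple(sorted(drivers)))
        a = sample_training_pixels(sm, maps[0], maps[1], drivers, 50, seed=9)
        b = sample_training_pixels(sm, maps[0], maps[1], drivers, 50, seed=9)
        np.testing.assert_array_equal(a.X_train, b.X_train)
        np.testing.assert_array_equal(a.y_valid, b.y_valid)

    def test_missing_transition_raises(self, strong_signal):
        cfg, drivers, maps, _ = strong_signal
        frozen = w.CategoricalRaster(maps[0].grid, maps[0].values.copy(), legend=None)
        sm = SubModel(transitions=((5, 2),), driver_names=tuple(sorted(drivers)))
        with pytest.raises(ValueError, match="5->2"):
            sample_training_pixels(sm, frozen, frozen, drivers, 50, seed=1)

    def test_balanced_class_proportions(self, strong_signal):
        _, drivers, maps, _ = strong_signal
        sm = SubModel(transitions=((2, 5),), driver_names=tuple(sorted(drivers)))
        ts = sample_training_pixels(sm, maps[0], maps[1], drivers, n_per_class=80, seed=5)
        y = np.concatenate([ts.y_train, ts.y_valid])
        counts = np.bincount(y)
        assert np.all(counts <= 80)
        assert counts.max() - counts.min() <= 1 or counts.min() * 1.0 / 80 < 1.0


class TestTraining:
    def test_linearly_separable_transitions_learned_almost_perfectly(self, rng):
        from wetdyn.transition_mlp import TrainingSet

        X = rng.normal(size=(800, 2))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        sm = SubModel(transitions=((2, 5),), driver_names=("a", "b"))
        ts = TrainingSet(sm, X[:400], y[:400], X[400:], y[400:], ["2->5", "persist_2"])
        _, report = train_mlp(ts, MlpConfig(iterations=3000, seed=0))
        assert report.accuracy_rate >= 0.95

    def test_strong_driver_signal_learned(self, strong_signal):
        _, drivers, maps, _ = strong_signal
        sm = SubModel(transitions=((2, 5),), driver_names=("dist_river", "dem"))
        ts = sample_training_pixels(sm, maps[0], maps[1], drivers, n_per_class=400, seed=2)
        model, report = train_mlp(ts, MlpConfig(iterations=3000, seed=2))
        assert report.accuracy_rate >= 0.80
        assert report.skill > 0.5

    def test_permuted_labels_have_no_skill(self, strong_signal, rng):
        _, drivers, maps, _ = strong_signal
        sm = SubModel(transitions=((2, 5),), driver_names=("dist_river", "dem"))
        ts = sample_training_pixels(sm, maps[0], maps[1], drivers, n_per_class=400, seed=2)
        ts.y_train = rng.permutation(ts.y_train)
        ts.y_valid = rng.permutation(ts.y_valid)
        _, report = train_mlp(ts, FAST)
        assert abs(report.skill) < 0.15

    def test_determinism_of_trained_weights(self, strong_signal):
        _, drivers, maps, _ = strong_signal
        sm = SubModel(transitions=((2, 5),), driver_names=("dist_river", "dem"))
        ts = sample_training_pixels(sm, maps[0], maps[1], drivers, n_per_class=100, seed=4)
        m1, _ = train_mlp(ts, FAST)
        m2, _ = train_mlp(ts, FAST)
        for a, b in zip(m1.classifier.coefs_, m2.classifier.coefs_):
            np.testing.assert_array_equal(a, b)

    def test_model_json_round_trip(self, strong_signal, tmp_path):
        _, drivers, maps, _ = strong_signal
        sm = SubModel(transitions=((2, 5),), driver_names=("dist_river", "dem"))
        ts = sample_training_pixels(sm, maps[0], maps[1], drivers, n_per_class=50, seed=4)
        model, _ = train_mlp(ts, FAST)
        path = tmp_path / "model.json"
        model.save_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["transitions"] == [[2, 5]]
        assert len(payload["coefs"]) == 2  # input->hidden, hidden->output


class TestPotentials:
    def test_bounded_and_nodata_propagated(self, strong_signal):
        _, drivers, maps, _ = strong_signal
        sm = SubModel(transitions=((2, 5),), driver_names=("dist_river", "dem"))
        ts = sample_training_pixels(sm, maps[0], maps[1], drivers, n_per_class=200, seed=6)
        model, _ = train_mlp(ts, FAST)
        holey = dict(drivers)
        vals = drivers["dem"].values.copy()
        vals[0, 0] = -9999.0
        holey["dem"] = w.ContinuousRaster(drivers["dem"].grid, vals, nodata_value=-9999.0)
        stack = w.predict_potentials(model, holey)
        surf = stack.potentials[(2, 5)]
        assert surf.values[0, 0] == surf.nodata_value
        valid = surf.valid_mask
        assert np.all((surf.values[valid] >= 0) & (surf.values[valid] <= 1))

    def test_constant_drivers_give_constant_potentials(self, strong_signal):
        _, drivers, maps, _ = strong_signal
        sm = SubModel(transitions=((2, 5),), driver_names=("dist_river", "dem"))
        ts = sample_training_pixels(sm, maps[0], maps[1], drivers, n_per_class=100, seed=6)
        model, _ = train_mlp(ts, FAST)
        grid = drivers["dem"].grid
        flat = {
            "dist_river": w.ContinuousRaster(grid, np.full(grid.shape, 500.0)),
            "dem": w.ContinuousRaster(grid, np.full(grid.shape, 80.0)),
        }
        stack = w.predict_potentials(model, flat)
        assert np.ptp(stack.potentials[(2, 5)].values) == 0.0

    def test_changed_cells_score_higher_than_persistent(self, strong_signal):
        """Held-out step: true future changes sit on higher potentials."""
        _, drivers, maps, _ = strong_signal
        sm = SubModel(transitions=((2, 5),), driver_names=("dist_river", "dem"))
        ts = sample_training_pixels(sm, maps[0], maps[1], drivers, n_per_class=400, seed=8)
        model, _ = train_mlp(ts, MlpConfig(iterations=3000, seed=8))
        stack = w.predict_potentials(model, drivers)
        pot = stack.potentials[(2, 5)].values
        water = maps[1].values == 2
        changed = water & (maps[2].values == 5)
        persistent = water & (maps[2].values == 2)
        assert pot[changed].mean() > pot[persistent].mean()

    def test_potentials_track_true_transition_probability(self, strong_signal):
        """Spearman correlation with the generator's per-cell probability."""
        cfg, drivers, maps, _ = strong_signal
        sm = SubModel(transitions=((2, 5),), driver_names=("dist_river", "dem"))
        ts = sample_training_pixels(sm, maps[0], maps[1], drivers, n_per_class=400, seed=10)
        model, _ = train_mlp(ts, MlpConfig(iterations=3000, seed=10))
        pot = w.predict_potentials(model, drivers).potentials[(2, 5)].values
        # generator's true per-cell water->salt probability
        z_river = (drivers["dist_river"].values - drivers["dist_river"].values.mean()) / drivers[
            "dist_river"
        ].values.std()
        z_dem = (drivers["dem"].values - drivers["dem"].values.mean()) / drivers["dem"].values.std()
        base = cfg.true_P[1]
        logits = np.log(base)[None, None, :] + np.zeros(maps[0].grid.shape + (5,))
        logits[:, :, 4] += 4.0 * z_river - 2.0 * z_dem
        probs = np.exp(logits - logits.max(axis=2, keepdims=True))
        true_p = (probs / probs.sum(axis=2, keepdims=True))[:, :, 4]
        water = maps[0].values == 2
        rho = stats.spearmanr(pot[water], true_p[water]).statistic
        assert rho > 0.3

    def test_missing_driver_listed_in_error(self, strong_signal):
        _, drivers, maps, _ = strong_signal
        sm = SubModel(transitions=((2, 5),), driver_names=("dist_river", "dem"))
        ts = sample_training_pixels(sm, maps[0], maps[1], drivers, n_per_class=50, seed=6)
        model, _ = train_mlp(ts, FAST)
        with pytest.raises(KeyError, match="dem"):
            w.predict_potentials(model, {"dist_river": drivers["dist_river"]})


class TestSkill:
    @pytest.mark.parametrize(
        "accuracy,n_outputs,expected",
        [(1.0, 4, 1.0), (0.25, 4, 0.0), (0.75, 2, 0.5)],
    )
    def test_closed_forms(self, accuracy, n_outputs, expected):
        assert w.skill_statistic(accuracy, n_outputs) == pytest.approx(expected)

    def test_fewer_than_two_outputs_rejected(self):
        with pytest.raises(ValueError):
            w.skill_statistic(0.9, 1)
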