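"""Neural models: features, splits, scaling, training protocol, inference."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.neural_network import MLPRegressor

import densrisk as dr
from densrisk.exceptions import ConfigurationError, DivergenceError, NotFittedError
from densrisk.networks import apply_scaler, fit_scaler
from densrisk.networks import engine
from densrisk.simulate import Cohort


class TestFeatures:
    def test_age_and_age_squared_columns(self):
        np.testing.assert_array_equal(dr.make_features(np.array([50.0])), [[50.0, 2500.0]])
        np.testing.assert_array_equal(
            dr.make_features(np.array([25.0, 85.0])), [[25.0, 625.0], [85.0, 7225.0]]
        )

    def test_shape_for_cohort_sized_input(self):
        assert dr.make_features(np.linspace(25, 85, 1000)).shape == (1000, 2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            dr.make_features(np.array([]))


class TestSplit:
    def test_80_20_sizes(self, default_cohort):
        train, test = dr.split_cohort(default_cohort, 0.8, seed=0)
        assert len(train) == 800 and len(test) == 200

    def test_same_seed_identical_split(self, default_cohort):
        a = dr.split_cohort(default_cohort, 0.8, seed=5)
        b = dr.split_cohort(default_cohort, 0.8, seed=5)
        assert a[0].data.equals(b[0].data) and a[1].data.equals(b[1].data)

    def test_three_seeds_distinct_partitions_union_is_cohort(self, default_cohort):
        whole = default_cohort.data.sort_values("age").reset_index(drop=True)
        train_sets = []
        for seed in (1, 2, 3):
            train, test = dr.split_cohort(default_cohort, 0.8, seed=seed)
            union = pd.concat([train.data, test.data]).sort_values("age").reset_index(drop=True)
            pd.testing.assert_frame_equal(union, whole)
            train_sets.append(frozenset(train.data["age"]))
        assert len(set(train_sets)) == 3

    def test_bad_fraction_rejected(self, default_cohort):
        with pytest.raises(ConfigurationError, match="train_fraction"):
            dr.split_cohort(default_cohort, 1.2, seed=0)


class TestScaler:
    def test_closed_form_three_values(self):
        scaler = fit_scaler(np.array([[1.0], [2.0], [3.0]]))
        scaled = apply_scaler(scaler, np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(scaled.ravel(), [-1.224744871, 0.0, 1.224744871], atol=1e-8)

    def test_training_columns_standardized(self):
        rng = np.random.default_rng(1)
        X = rng.normal(5, 3, size=(100, 2))
        scaled = apply_scaler(fit_scaler(X), X)
        np.testing.assert_allclose(scaled.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(scaled.std(axis=0), 1.0, atol=1e-9)

    def test_test_set_uses_training_statistics(self):
        rng = np.random.default_rng(2)
        scaler = fit_scaler(rng.normal(0, 1, size=(100, 1)))
        shifted = apply_scaler(scaler, rng.normal(3, 1, size=(50, 1)))
        assert abs(shifted.mean()) > 1.0  # disjoint set is not recentered

    def test_zero_variance_column_rejected(self):
        with pytest.raises(ConfigurationError, match="spread"):
            fit_scaler(np.ones((10, 2)))


class TestGlorotInit:
    def test_weights_within_glorot_uniform_limits(self):
        rng = np.random.default_rng(0)
        layer = engine.Dense(40, 60, rng=rng)
        limit = np.sqrt(6.0 / (40 + 60))
        assert np.all(np.abs(layer.W) <= limit)
        assert abs(layer.W.mean()) < 0.01
        np.testing.assert_array_equal(layer.b, 0.0)


class TestTrainingProtocol:
    def test_seeded_determinism_end_to_end(self, default_split):
        train, test = default_split
        cfg = dr.NetworkConfig(seed=3, max_epochs=20, patience=20)
        m1 = dr.train_bifurcated(train, cfg)
        m2 = dr.train_bifurcated(train, cfg)
        ages = test.age
        for name in m1.outputs:
            np.testing.assert_array_equal(m1.predict(ages)[name], m2.predict(ages)[name])
        assert m1.stopped_epoch == m2.stopped_epoch
        assert m1.training_history == m2.training_history

    def test_different_model_seeds_differ(self, default_split):
        train, test = default_split
        cfg = dr.NetworkConfig(max_epochs=10, patience=10)
        m1 = dr.train_bifurcated(train, cfg.replace(seed=0))
        m2 = dr.train_bifurcated(train, cfg.replace(seed=1))
        assert not np.array_equal(
            m1.predict(test.age)["densitanum"], m2.predict(test.age)["densitanum"]
        )

    def test_single_epoch_contract(self, default_split):
        train, _ = default_split
        model = dr.train_mlp(train, "riskenum", dr.NetworkConfig(max_epochs=1, patience=1))
        assert model.stopped_epoch == 1
        assert len(model.training_history) == 1

    def test_flat_validation_loss_stops_within_patience(self, default_split):
        # zero learning rate plus disabled batch norm freezes the forward
        # pass entirely, so validation loss is flat from epoch 1 and
        # training must stop by epoch 1 + patience
        train, _ = default_split
        cfg = dr.NetworkConfig(learning_rate=0.0, patience=10, max_epochs=300, batch_norm=False)
        model = dr.train_bifurcated(train, cfg)
        assert model.stopped_epoch <= 11

    def test_early_stopping_restores_best_validation_weights(self, bif_default):
        history_val = [h["val_loss"] for h in bif_default.training_history]
        assert bif_default.stopped_epoch <= bif_default.config.max_epochs
        # restored weights correspond to the minimum validation loss seen
        assert min(history_val) <= history_val[-1]

    def test_non_finite_loss_raises_divergence_error(self):
        frame = pd.DataFrame(
            {
                "age": np.linspace(30, 80, 50),
                "densitanum": np.r_[np.nan, np.ones(49)],
                "riskenum": np.full(50, 13.0),
            }
        )
        with pytest.raises(DivergenceError) as err:
            dr.train_bifurcated(Cohort(frame), dr.NetworkConfig(max_epochs=5, patience=5))
        assert err.value.epoch == 1


class TestPredict:
    def test_inference_is_deterministic(self, bif_default):
        ages = np.array([30.0, 50.0, 70.0])
        a = bif_default.predict(ages)
        b = bif_default.predict(ages)
        for name in bif_default.outputs:
            np.testing.assert_array_equal(a[name], b[name])

    def test_single_age_matches_batch(self, bif_default):
        single = bif_default.predict(np.array([55.0]))
        batch = bif_default.predict(np.array([40.0, 55.0, 70.0]))
        for name in bif_default.outputs:
            assert single[name][0] == pytest.approx(batch[name][1], abs=1e-6)

    def test_unfitted_model_raises_state_error(self, bif_default):
        import dataclasses

        broken = dataclasses.replace(bif_default, net=None)
        with pytest.raises(NotFittedError):
            broken.predict(np.array([50.0]))

    def test_noiseless_model_learns_declining_density_trend(self, bif_noiseless):
        # the generative quadratic peaks at age 25, so predicted density must
        # decline across the age range
        grid = np.arange(30.0, 85.0, 10.0)
        dens = bif_noiseless.predict(grid)["densitanum"]
        assert np.all(np.diff(dens) < 0.05)
        assert dens[0] > dens[-1]


class TestAgainstEstablishedImplementation:
    def test_sklearn_mlp_agrees_on_noiseless_task(self, noiseless_split):
        """Independent cross-check: an established MLP implementation reaches
        the same near-perfect accuracy on the noiseless density task, so the
        in-package engine's convergence is not an artifact."""
        train, test = noiseless_split
        ours = dr.train_mlp(train, "densitanum", dr.NetworkConfig(seed=0))
        ours_r2 = ours.evaluate(test)["densitanum"].r_squared

        X_tr = dr.make_features(train.age)
        scaler = fit_scaler(X_tr)
        ref = MLPRegressor(hidden_layer_sizes=(64, 32), activation="relu", solver="lbfgs",
                           max_iter=2000, random_state=0)
        ref.fit(apply_scaler(scaler, X_tr), train.densitanum)
        ref_r2 = 1 - np.mean(
            (ref.predict(apply_scaler(scaler, dr.make_features(test.age))) - test.densitanum) ** 2
        ) / np.var(test.densitanum)
        assert ours_r2 > 0.99
        assert ref_r2 > 0.99
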