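"""Reduction, network arithmetic, training behavior, persistence."""

import warnings

import numpy as np
import pytest

from gbsolv import (FeatureReducer, SolvationModel, SolvationNetwork,
                    apply_transform, count_parameters, default_schema,
                    fit_transform_spec, regression_metrics, train_model)


class TestCountParameters:
    def test_published_architectures(self):
        assert count_parameters([49, 16, 8, 1]) == 945
        assert count_parameters([52, 14, 7, 1]) == 855

    def test_tiny_stack(self):
        # (2+1)*2 + (2+1)*1 = 9
        assert count_parameters([2, 2, 1]) == 9


class TestRegressionMetrics:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0])
        m = regression_metrics(y, y)
        assert m["rmse"] == 0.0
        assert m["slope"] == pytest.approx(1.0)
        assert m["r2"] == pytest.approx(1.0)

    def test_constant_offset(self):
        y = np.array([0.0, 1.0, 2.0])
        m = regression_metrics(y, y + 0.5)
        assert m["mse"] == pytest.approx(0.5)  # mean signed error
        assert m["mae"] == pytest.approx(0.5)
        assert m["rmse"] == pytest.approx(0.5)
        assert m["intercept"] == pytest.approx(0.5)


class TestFeatureReducer:
    def _data(self, n=300, d=12, seed=0):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(d, d))
        return rng.normal(size=(n, d)) @ A

    def test_output_dimension(self):
        X = self._data()
        red = FeatureReducer(n_drop=3).fit(X)
        assert red.transform(X).shape == (300, 9)

    def test_transform_is_affine(self):
        X = self._data()
        red = FeatureReducer(n_drop=3).fit(X)
        rng = np.random.default_rng(1)
        a, b, c = rng.normal(size=(3, 12))
        lhs = red.transform((a + b - c)[None])[0]
        rhs = (red.transform(a[None]) + red.transform(b[None])
               - red.transform(c[None]))[0]
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_unit_variance_components(self):
        X = self._data()
        red = FeatureReducer(n_drop=3).fit(X)
        Z = red.transform(X)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-9)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-9)

    def test_lossless_when_nothing_dropped(self):
        X = self._data()
        red = FeatureReducer(n_drop=0).fit(X)
        Z = red.transform(X)
        # invert: unscale, rotate back, un-z-score
        back = (Z * red.comp_scale_) @ red.components_ * red.scale_ + red.center_
        assert np.allclose(back, X, atol=1e-8)

    def test_sign_convention(self):
        red = FeatureReducer(n_drop=3).fit(self._data())
        for row in red.components_:
            assert row[np.argmax(np.abs(row))] > 0

    def test_orthonormal_components(self):
        red = FeatureReducer(n_drop=3).fit(self._data())
        G = red.components_ @ red.components_.T
        assert np.allclose(G, np.eye(9), atol=1e-9)

    def test_duplicate_column_spectrum(self):
        """An exactly duplicated column adds no variance: the smallest
        component is null and dropping it loses nothing."""
        X = self._data()
        Xdup = np.hstack([X, X[:, :1]])
        red = FeatureReducer(n_drop=1).fit(Xdup)
        Z = (Xdup - red.center_) / red.scale_
        total = Z.var(axis=0).sum()
        # the 12 kept components capture the full z-scored variance
        assert np.sum(red.explained_variance_) * (len(Z) - 1) / len(Z) == (
            pytest.approx(total, rel=1e-6)
        )
        assert red.transform(Xdup).shape[1] == 12

    def test_wrong_width_rejected(self):
        red = FeatureReducer(n_drop=3).fit(self._data())
        with pytest.raises(ValueError):
            red.transform(np.zeros((1, 5)))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            FeatureReducer(n_drop=0).fit(np.random.default_rng(0).normal(size=(5, 12)))

    def test_wrappers(self):
        X = self._data()
        red = fit_transform_spec(X, n_drop=3)
        one = apply_transform(red, X[0])
        assert one.shape == (9,)
        assert np.allclose(one, red.transform(X[:1])[0])


class TestNetworkForward:
    def _hand_net(self):
        net = SolvationNetwork(hidden_layer_sizes=(2,))
        net.n_features_in_ = 2
        net.weights_ = [np.array([[1.0, -1.0], [0.0, 2.0]]),
                        np.array([[1.0], [1.0]])]
        net.biases_ = [np.array([0.0, 0.5]), np.array([0.25])]
        return net

    def test_hand_computed_forward_pass(self):
        net = self._hand_net()
        # x = (1, 1): pre = (1, 1.5) -> relu same -> out = 1 + 1.5 + 0.25
        assert net.predict([[1.0, 1.0]])[0] == pytest.approx(2.75)
        # x = (1, 0): pre = (1, -0.5) -> relu (1, 0) -> out = 1.25
        assert net.predict([[1.0, 0.0]])[0] == pytest.approx(1.25)

    def test_all_units_dead_gives_output_bias(self):
        net = self._hand_net()
        # strongly negative preactivations: prediction = output bias
        assert net.predict([[-50.0, -50.0]])[0] == pytest.approx(0.25)

    def test_wrong_width_rejected(self):
        with pytest.raises(ValueError):
            self._hand_net().predict(np.zeros((1, 7)))


class TestNetworkTraining:
    def _problem(self, n=300, d=6, sigma=0.1, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, d))
        coef = rng.normal(size=d)
        y = 1.5 + X @ coef + rng.normal(0, sigma, size=n)
        return X, y, coef

    def test_seed_determinism(self):
        X, y, _ = self._problem()
        kw = dict(hidden_layer_sizes=(8, 4), epochs=30, seed=3)
        a = SolvationNetwork(**kw).fit(X, y)
        b = SolvationNetwork(**kw).fit(X, y)
        for Wa, Wb in zip(a.weights_, b.weights_):
            assert np.array_equal(Wa, Wb)
        assert np.array_equal(a.predict(X), b.predict(X))

    def test_zero_weight_records_ignored(self):
        X, y, _ = self._problem(n=120)
        Xbad = np.vstack([X, 100 * np.ones((1, X.shape[1]))])
        ybad = np.append(y, 1e6)
        w = np.append(np.ones(len(y)), 0.0)
        kw = dict(hidden_layer_sizes=(8, 4), epochs=20, seed=0)
        ref = SolvationNetwork(**kw).fit(X, y)
        got = SolvationNetwork(**kw).fit(Xbad, ybad, sample_weight=w)
        for Wa, Wb in zip(ref.weights_, got.weights_):
            assert np.array_equal(Wa, Wb)

    def test_negative_weight_rejected(self):
        X, y, _ = self._problem(n=50)
        with pytest.raises(ValueError):
            SolvationNetwork(epochs=1).fit(X, y, sample_weight=-np.ones(50))

    def test_huge_l2_collapses_to_constant(self):
        X, y, _ = self._problem(n=200)
        net = SolvationNetwork(hidden_layer_sizes=(8, 4), epochs=150,
                               l2=1e4, seed=0, patience=None)
        net.fit(X, y)
        pred = net.predict(X)
        assert pred.std() < 0.05 * y.std()

    def test_linear_recovery_against_ols_oracle(self):
        """Labels linear in the inputs + sigma=0.1 noise: validation RMSE
        approaches sigma, and is comparable to the OLS oracle."""
        X, y, coef = self._problem(n=600, d=6, sigma=0.1, seed=2)
        net = SolvationNetwork(hidden_layer_sizes=(16, 8), epochs=300, seed=2)
        net.fit(X, y)
        # OLS oracle on the same data
        A = np.hstack([X, np.ones((len(y), 1))])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        ols_rmse = np.sqrt(np.mean((A @ beta - y) ** 2))
        assert ols_rmse == pytest.approx(0.1, abs=0.03)
        assert net.val_metrics_["rmse"] < 3.5 * ols_rmse

    def test_history_and_metrics_populated(self):
        X, y, _ = self._problem(n=100)
        net = SolvationNetwork(hidden_layer_sizes=(4, 2), epochs=10, seed=0)
        net.fit(X, y)
        assert len(net.history_["loss"]) == 10
        assert len(net.history_["val_loss"]) == 10
        assert set(net.train_metrics_) >= {"mse", "mae", "rmse"}
        assert net.n_parameters_ == count_parameters([X.shape[1], 4, 2, 1])

    def test_underdetermined_warning(self):
        X, y, _ = self._problem(n=30)
        with pytest.warns(UserWarning, match="parameters"):
            SolvationNetwork(hidden_layer_sizes=(16, 8), epochs=2).fit(X, y)


class TestPersistence:
    def _small_model(self, tmp_path, aqueous=True):
        rng = np.random.default_rng(0)
        schema = default_schema(aqueous=aqueous)
        X = rng.normal(size=(150, schema.raw_dim))
        y = rng.normal(size=150)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return train_model(X, y, schema, n_drop=9, epochs=5, seed=0)

    def test_round_trip_predictions(self, tmp_path):
        model = self._small_model(tmp_path)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, model.schema.raw_dim))
        path = tmp_path / "model.json"
        model.save(path)
        back = SolvationModel.load(path)
        assert np.allclose(back.predict_raw(X), model.predict_raw(X), atol=1e-12)
        assert back.schema.aqueous == model.schema.aqueous
        assert back.schema.pair_list == model.schema.pair_list

    def test_bad_archive_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError):
            SolvationModel.load(path)

    def test_train_model_architecture_selection(self, tmp_path):
        aq = self._small_model(tmp_path, aqueous=True)
        non = self._small_model(tmp_path, aqueous=False)
        assert aq.network.n_parameters_ == 945
        assert non.network.n_parameters_ == 855

    def test_predict_molecule_runs(self, tmp_path, water_like):
        from gbsolv import lookup_solvent

        model = self._small_model(tmp_path)
        val = model.predict_molecule(water_like, lookup_solvent("water"))
        assert np.isfinite(val)
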