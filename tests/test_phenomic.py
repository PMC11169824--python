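"""Phenomic deep-network predictor: metrics, architecture, training,
tuning and forward prediction."""

import numpy as np
import pandas as pd
import pytest

import phenogs as pg
from phenogs.phenomic import (
    DNNConfig,
    build_model,
    evaluate,
    forward_predict,
    train_predict,
    tune,
)

SMALL = DNNConfig(hidden_sizes=(32, 32), dropout=0.1, epochs=60, batch_size=32, seed=1)


def _toy_features(n=300, n_feats=8, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_feats))
    w = rng.normal(size=n_feats)
    y = X @ w + noise * rng.normal(size=n)
    df = pd.DataFrame(X, columns=[f"VI{j}@F8" for j in range(n_feats)])
    df["GY"] = y
    df.attrs["feature_columns"] = list(df.columns[:-1])
    df.attrs["target_columns"] = ["GY"]
    return df


class TestMetrics:
    def test_perfect_and_null_predictions(self):
        y = np.array([2.0, 4.0, 6.0, 8.0])
        m = evaluate(y, y)
        assert m.r2 == pytest.approx(1.0) and m.rmse == pytest.approx(0.0)
        null = evaluate(np.full(4, y.mean()), y)
        assert null.r2 == pytest.approx(0.0)

    def test_worked_triple(self):
        m = evaluate(np.array([1.0, 2.0, 4.0]), np.array([1.0, 2.0, 3.0]))
        assert m.r2 == pytest.approx(0.5)
        assert m.rmse == pytest.approx(0.7071, abs=5e-5)
        assert m.rmse_pct == pytest.approx(35.36, abs=5e-3)

    def test_rmse_uses_n_minus_one_denominator(self):
        m = evaluate(np.array([1.0, 2.0, 4.0]), np.array([1.0, 2.0, 3.0]))
        assert m.rmse == pytest.approx(np.sqrt(1.0 / 2.0))
        assert m.rmse != pytest.approx(np.sqrt(1.0 / 3.0))

    def test_zero_mean_flags_relative_rmse(self):
        with pytest.warns(UserWarning):
            m = evaluate(np.array([1.0, -1.0, 0.5]), np.array([1.0, -1.0, 0.0]))
        assert np.isnan(m.rmse_pct)


class TestArchitecture:
    def test_default_widths(self):
        assert DNNConfig().hidden_sizes == (64, 128, 256, 512, 1024)

    def test_parameter_count_matches_dense_arithmetic(self):
        cfg = DNNConfig(hidden_sizes=(4, 3), use_batch_norm=False, dropout=0.0)
        model = build_model(cfg, n_features=5)
        assert model.n_parameters() == (5 * 4 + 4) + (4 * 3 + 3) + (3 * 1 + 1)
        cfg_bn = DNNConfig(hidden_sizes=(4, 3), use_batch_norm=True, dropout=0.0)
        assert build_model(cfg_bn, 5).n_parameters() == 43 + 2 * 4 + 2 * 3

    def test_degenerate_config_is_affine(self):
        cfg = DNNConfig(hidden_sizes=(1,), dropout=0.0, use_batch_norm=False,
                        activation="identity", seed=3)
        model = build_model(cfg, n_features=2)
        a, b = np.array([[1.0, 2.0]]), np.array([[-3.0, 0.5]])
        mid = model.predict((a + b) / 2)
        assert model.predict(a) + model.predict(b) == pytest.approx(2 * mid, abs=1e-10)

    def test_empty_hidden_sizes_rejected(self):
        with pytest.raises(ValueError):
            DNNConfig(hidden_sizes=())


class TestTraining:
    def test_learns_linear_map(self):
        fm = _toy_features(n=300, seed=5)
        _, m = train_predict(fm, "GY", SMALL)
        assert m.r2 >= 0.9

    def test_same_seed_bitwise_identical(self):
        fm = _toy_features(n=120, seed=7)
        cfg = DNNConfig(hidden_sizes=(16,), epochs=20, seed=9)
        _, m1 = train_predict(fm, "GY", cfg)
        _, m2 = train_predict(fm, "GY", cfg)
        assert m1.r2 == m2.r2 and m1.rmse == m2.rmse

    def test_too_few_plots_rejected(self):
        with pytest.raises(ValueError):
            train_predict(_toy_features(n=10), "GY", SMALL)


class TestTune:
    def test_single_cell_grid_returned(self):
        fm = _toy_features(n=150, seed=11)
        best, report = tune(fm, "GY", epochs_grid=(15,), batch_grid=(32,),
                            base=DNNConfig(hidden_sizes=(16,), seed=1))
        assert best.epochs == 15 and best.batch_size == 32
        assert len(report) == 1

    def test_longer_training_wins_on_learnable_signal(self):
        fm = _toy_features(n=200, seed=13)
        best, report = tune(fm, "GY", epochs_grid=(1, 60), batch_grid=(32,),
                            base=DNNConfig(hidden_sizes=(16,), dropout=0.0, seed=1))
        assert best.epochs == 60
        assert len(report) == 2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tune(_toy_features(), "GY", epochs_grid=(), batch_grid=(16,))


class TestForward:
    def test_column_mismatch_rejected(self):
        fm = _toy_features(n=60, seed=15)
        other = _toy_features(n=60, n_feats=4, seed=15)
        with pytest.raises(ValueError):
            forward_predict(fm, other, "GY", SMALL)

    def test_identical_train_test_equals_in_sample(self):
        fm = _toy_features(n=100, seed=17)
        cfg = DNNConfig(hidden_sizes=(32,), epochs=150, dropout=0.0, seed=19)
        m1 = forward_predict(fm, fm, "GY", cfg)
        m2 = forward_predict(fm, fm, "GY", cfg)
        assert m1.r2 == m2.r2  # deterministic, and by construction in-sample
        assert m1.r2 > 0.9

    def test_generalization_gap(self):
        """Forward prediction onto an independently drawn set scores below
        in-sample accuracy."""
        tr = _toy_features(n=200, noise=0.5, seed=21)
        # rebuild the same weight vector to draw an independent test set
        rng = np.random.default_rng(21)
        rng.normal(size=(200, 8))
        w = rng.normal(size=8)
        rng2 = np.random.default_rng(99)
        X2 = rng2.normal(size=(200, 8))
        te = pd.DataFrame(X2, columns=tr.attrs["feature_columns"])
        te["GY"] = X2 @ w + 0.5 * rng2.normal(size=200)
        te.attrs.update(tr.attrs)
        cfg = DNNConfig(hidden_sizes=(16,), epochs=60, dropout=0.0, seed=23)
        in_sample = forward_predict(tr, tr, "GY", cfg)
        fwd = forward_predict(tr, te, "GY", cfg)
        assert fwd.r2 < in_sample.r2
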