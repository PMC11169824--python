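"""Deep-network phenomic prediction of agronomic traits from multitemporal
vegetation-index features.

A feedforward network (default five hidden layers of 64, 128, 256, 512 and
1024 units, batch normalization, ReLU, dropout 0.3, linear output, MSE loss,
Adam) maps plot-level (index, stage) features to grain yield, test weight or
grain protein. Evaluation uses the coefficient of determination, the RMSE
with an n-1 denominator, and the relative RMSE (% of the test-set mean).

Also provides the epoch x batch-size grid search, the per-stage ablation
harness, and forward prediction (train on advanced-trial plots, predict
preliminary-trial plots with standardization parameters learned on the
training data only).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._nn import MLP

logger = logging.getLogger(__name__)

#: Hyperparameter search ranges for the grid search.
EPOCH_GRID = (50, 100, 150, 200, 250)
BATCH_GRID = (16, 24, 32, 64)


@dataclass(frozen=True)
class DNNConfig:
    """Network and training settings (defaults mirror the reference
    architecture: widths 64..1024, dropout 0.3, batch norm, ReLU hidden /
    linear output, MSE + Adam, 70/30 train-test split)."""

    hidden_sizes: tuple[int, ...] = (64, 128, 256, 512, 1024)
    dropout: float = 0.3
    use_batch_norm: bool = True
    activation: str = "relu"
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    split_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be non-empty")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")


@dataclass
class EvalMetrics:
    """Test-set regression metrics."""

    r2: float
    rmse: float
    rmse_pct: float
    n: int
    y_bar: float

    def __str__(self):
        return f"R2={self.r2:.3f}  RMSE={self.rmse:.3f}  RMSE%={self.rmse_pct:.2f}  (n={self.n})"


def evaluate(predicted: np.ndarray, observed: np.ndarray) -> EvalMetrics:
    """R2, RMSE (n-1 denominator) and relative RMSE of predictions.

    ``R2 = 1 - sum (y - yhat)^2 / sum (y - ybar)^2``;
    ``RMSE = sqrt(sum (y - yhat)^2 / (n - 1))``; ``RMSE% = RMSE/ybar*100``
    (flagged NaN when the observed mean is zero).
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    n = len(observed)
    if n < 2:
        raise ValueError("need at least 2 observations")
    ss_res = float(np.sum((observed - predicted) ** 2))
    y_bar = float(np.mean(observed))
    ss_tot = float(np.sum((observed - y_bar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    rmse = float(np.sqrt(ss_res / (n - 1)))
    if y_bar == 0:
        warnings.warn("observed mean is zero: RMSE%% undefined", stacklevel=2)
        rmse_pct = np.nan
    else:
        rmse_pct = rmse / y_bar * 100.0
    return EvalMetrics(r2=r2, rmse=rmse, rmse_pct=rmse_pct, n=n, y_bar=y_bar)


def build_model(cfg: DNNConfig, n_features: int, n_outputs: int = 1) -> MLP:
    """Instantiate the network for a given feature count."""
    if n_features < 1:
        raise ValueError("need at least one feature")
    return MLP(
        n_features,
        cfg.hidden_sizes,
        n_outputs=n_outputs,
        dropout=cfg.dropout,
        use_batch_norm=cfg.use_batch_norm,
        activation=cfg.activation,
        seed=cfg.seed,
    )


def _xy(features: pd.DataFrame, target: str):
    feat_cols = features.attrs.get("feature_columns")
    if feat_cols is None:
        targets = features.attrs.get("target_columns", ("GY", "TW", "GPC"))
        feat_cols = [c for c in features.columns if c not in targets]
    if target not in features.columns:
        raise KeyError(f"target {target!r} not in feature matrix")
    X = features[list(feat_cols)].to_numpy(dtype=float)
    y = features[target].to_numpy(dtype=float)
    return X, y, list(feat_cols)


class _Standardizer:
    """Per-feature z-scoring with parameters learned on training data only."""

    def fit(self, X):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X):
        return (X - self.mean) / self.sd


def _train_on(X_train, y_train, cfg: DNNConfig):
    sx = _Standardizer().fit(X_train)
    y_mean, y_sd = float(np.mean(y_train)), float(np.std(y_train))
    y_sd = y_sd if y_sd > 0 else 1.0
    model = build_model(cfg, X_train.shape[1])
    model.fit(sx.transform(X_train), (y_train - y_mean) / y_sd,
              epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.learning_rate)

    def predict(X):
        return model.predict(sx.transform(X)) * y_sd + y_mean

    return model, predict


def train_predict(
    features: pd.DataFrame, target: str, cfg: DNNConfig | None = None
) -> tuple[MLP, EvalMetrics]:
    """Random 70/30 plot split, train on 70%, return held-out metrics.

    The split, weight initialization, dropout masks and batch order are all
    driven by ``cfg.seed``, so repeated runs are identical.
    """
    cfg = cfg or DNNConfig()
    X, y, _ = _xy(features, target)
    if len(y) < 20:
        raise ValueError("need at least 20 plots")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(len(y))
    n_train = int(np.floor(cfg.split_fraction * len(y)))
    tr, te = perm[:n_train], perm[n_train:]
    model, predict = _train_on(X[tr], y[tr], cfg)
    metrics = evaluate(predict(X[te]), y[te])
    return model, metrics


def tune(
    features: pd.DataFrame,
    target: str,
    epochs_grid=EPOCH_GRID,
    batch_grid=BATCH_GRID,
    base: DNNConfig | None = None,
) -> tuple[DNNConfig, pd.DataFrame]:
    """Grid search over epochs x batch size on a validation split.

    A validation fifth is carved out of the 70% training portion; every
    grid cell is trained on the rest and scored by validation MSE. Ties go
    to fewer epochs, then smaller batch. Failed cells are logged and
    skipped. Returns (best config, grid report).
    """
    base = base or DNNConfig()
    if not epochs_grid or not batch_grid:
        raise ValueError("empty hyperparameter grid")
    X, y, _ = _xy(features, target)
    rng = np.random.default_rng(base.seed)
    perm = rng.permutation(len(y))
    n_train = int(np.floor(base.split_fraction * len(y)))
    train_idx = perm[:n_train]
    n_fit = int(np.floor(0.8 * n_train))
    fit_idx, val_idx = train_idx[:n_fit], train_idx[n_fit:]
    rows = []
    for epochs in epochs_grid:
        for batch in batch_grid:
            cfg = replace(base, epochs=epochs, batch_size=batch)
            try:
                _, predict = _train_on(X[fit_idx], y[fit_idx], cfg)
                val_mse = float(np.mean((predict(X[val_idx]) - y[val_idx]) ** 2))
            except Exception as exc:  # noqa: BLE001 - cell failures are logged, not fatal
                logger.warning("grid cell (epochs=%d, batch=%d) failed: %s", epochs, batch, exc)
                continue
            rows.append({"epochs": epochs, "batch_size": batch, "val_mse": val_mse})
    report = pd.DataFrame(rows)
    if report.empty:
        raise RuntimeError("every grid cell failed")
    best = report.sort_values(["val_mse", "epochs", "batch_size"]).iloc[0]
    return replace(base, epochs=int(best["epochs"]), batch_size=int(best["batch_size"])), report


def forward_predict(
    train_features: pd.DataFrame,
    test_features: pd.DataFrame,
    target: str,
    cfg: DNNConfig | None = None,
) -> EvalMetrics:
    """Train on every advanced-trial plot (no internal split), predict the
    preliminary-trial plots. Feature standardization is learned on the
    training matrix only and applied unchanged to the test matrix."""
    cfg = cfg or DNNConfig()
    X_tr, y_tr, cols_tr = _xy(train_features, target)
    X_te, y_te, cols_te = _xy(test_features, target)
    if cols_tr != cols_te:
        raise ValueError("train and test feature columns differ")
    _, predict = _train_on(X_tr, y_tr, cfg)
    return evaluate(predict(X_te), y_te)


def stage_ablation(
    vi: pd.DataFrame,
    pheno: pd.DataFrame,
    target: str,
    cfg: DNNConfig | None = None,
    stages=None,
) -> pd.DataFrame:
    """Per-stage models versus the all-stage model, one row each."""
    from .spectral import STAGES, build_feature_matrix

    stages = list(stages) if stages is not None else [s for s in STAGES if s in set(vi["stage"])]
    rows = []
    for label, subset in [*[(s, [s]) for s in stages], ("all", stages)]:
        fm = build_feature_matrix(vi, pheno, stages=subset, targets=(target,))
        _, metrics = train_predict(fm, target, cfg)
        rows.append({"stages": label, "r2": metrics.r2, "rmse": metrics.rmse,
                     "rmse_pct": metrics.rmse_pct, "n_test": metrics.n})
    return pd.DataFrame(rows)
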