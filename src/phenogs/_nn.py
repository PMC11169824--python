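"""Minimal feedforward neural network in numpy.

Implements exactly what the phenomic predictor needs — dense layers, batch
normalization, ReLU, inverted dropout, mean-squared-error loss and the Adam
optimizer — with hand-written backpropagation. Float64 throughout; all
randomness (weight init, dropout masks, minibatch shuffling) flows from a
single ``numpy.random.Generator``, so training is bit-reproducible for a
fixed seed on a given machine.
"""

from __future__ import annotations

import numpy as np


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialization (ReLU networks)
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self._x = None

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def n_params(self):
        return self.W.size + self.b.size


class BatchNorm:
    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        self.dgamma = (grad * self._xhat).sum(axis=0)
        self.dbeta = grad.sum(axis=0)
        gx = grad * self.gamma
        if not self._training:
            return gx / self._std
        m = grad.shape[0]
        # standard batchnorm backward through batch statistics
        return (gx - gx.mean(axis=0) - self._xhat * (gx * self._xhat).mean(axis=0)) / self._std

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def n_params(self):
        return self.gamma.size + self.beta.size


class ReLU:
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask

    def params(self):
        return []

    def n_params(self):
        return 0


class Identity:
    def forward(self, x, training):
        return x

    def backward(self, grad):
        return grad

    def params(self):
        return []

    def n_params(self):
        return 0


class Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask

    def params(self):
        return []

    def n_params(self):
        return 0


class Adam:
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, layers):
        self.t += 1
        for layer in layers:
            for key, (name, p, g) in enumerate(layer.params()):
                sid = (id(layer), key)
                if sid not in self.state:
                    self.state[sid] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self.state[sid]
                m[:] = self.beta1 * m + (1 - self.beta1) * g
                v[:] = self.beta2 * v + (1 - self.beta2) * g * g
                mhat = m / (1 - self.beta1**self.t)
                vhat = v / (1 - self.beta2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class MLP:
    """Feedforward net: per hidden layer dense -> (batchnorm) -> activation
    -> (dropout); linear output head."""

    def __init__(
        self,
        n_features: int,
        hidden_sizes,
        n_outputs: int = 1,
        dropout: float = 0.3,
        use_batch_norm: bool = True,
        activation: str = "relu",
        seed: int = 0,
    ):
        if not hidden_sizes:
            raise ValueError("hidden_sizes must be non-empty")
        act_cls = {"relu": ReLU, "identity": Identity, "linear": Identity}.get(activation)
        if act_cls is None:
            raise ValueError(f"unknown activation {activation!r}")
        self.rng = np.random.default_rng(seed)
        self.layers = []
        n_in = n_features
        for width in hidden_sizes:
            self.layers.append(Dense(n_in, width, self.rng))
            if use_batch_norm:
                self.layers.append(BatchNorm(width))
            self.layers.append(act_cls())
            if dropout > 0:
                self.layers.append(Dropout(dropout, self.rng))
            n_in = width
        self.layers.append(Dense(n_in, n_outputs, self.rng))

    def forward(self, x, training=False):
        out = np.asarray(x, dtype=float)
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def n_parameters(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def fit(self, X, y, epochs: int, batch_size: int, lr: float = 1e-3):
        """Minimize MSE with Adam over shuffled minibatches.

        Returns the per-epoch training loss trace; raises on non-finite
        loss (diverged optimization).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        n = X.shape[0]
        opt = Adam(lr=lr)
        losses = []
        for epoch in range(epochs):
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = X[idx], y[idx]
                pred = self.forward(xb, training=True)
                diff = pred - yb
                loss = float(np.mean(diff**2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, batch {start // batch_size}"
                    )
                epoch_loss += loss * len(idx)
                self.backward(2.0 * diff / diff.size)
                opt.step(self.layers)
            losses.append(epoch_loss / n)
        return losses

    def predict(self, X):
        """Evaluation-mode forward pass (dropout off, batch-norm frozen at
        running statistics)."""
        out = self.forward(X, training=False)
        return out[:, 0] if out.shape[1] == 1 else out
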