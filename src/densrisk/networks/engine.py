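"""A compact, deterministic feed-forward engine in NumPy.

Implements exactly the primitives the study's two architectures need:
dense layers with optional ReLU and L2 weight penalty, batch
normalization, inverted dropout, Glorot-uniform initialization, the Adam
optimizer, mini-batch training with per-epoch shuffling, and early
stopping on validation loss with best-weight restoration. Everything
stochastic (initialization, shuffling, dropout masks) is driven by
`numpy.random.Generator` streams spawned from a single model seed, so a
training run is bit-reproducible.

Conventions follow the common deep-learning defaults: Adam with
beta1=0.9, beta2=0.999, eps=1e-7; batch normalization with momentum 0.99
and eps=1e-3; dropout scaled at train time (inference is a plain forward
pass). L2 penalty lambda*||W||^2 on the kernel it is attached to.
"""

from __future__ import annotations

import copy
from typing import Sequence

import numpy as np

from ..exceptions import DivergenceError


class Dense:
    """Fully connected layer, optional ReLU, optional L2 kernel penalty."""

    def __init__(self, n_in: int, n_out: int, *, relu: bool = False, l2: float = 0.0,
                 rng: np.random.Generator | None = None) -> None:
        limit = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
        rng = rng if rng is not None else np.random.default_rng()
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.relu = relu
        self.l2 = l2
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        if self.relu:
            self._mask = z > 0
            z = np.where(self._mask, z, 0.0)
        return z

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.relu:
            g = g * self._mask
        self.gW = self._x.T @ g + 2.0 * self.l2 * self.W
        self.gb = g.sum(axis=0)
        return g @ self.W.T

    def penalty(self) -> float:
        return float(self.l2 * np.sum(self.W**2))

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.gW, self.gb]


class BatchNorm:
    """Batch normalization with running statistics for inference."""

    def __init__(self, n_features: int, *, momentum: float = 0.99, eps: float = 1e-3) -> None:
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
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

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.ggamma = (g * self._xhat).sum(axis=0)
        self.gbeta = g.sum(axis=0)
        gx_hat = g * self.gamma
        if not self._training:
            return gx_hat / self._std
        n = g.shape[0]
        # standard batch-norm backward using batch statistics
        return (gx_hat - gx_hat.mean(axis=0) - self._xhat * (gx_hat * self._xhat).mean(axis=0)) / self._std

    def penalty(self) -> float:
        return 0.0

    @property
    def params(self) -> list[np.ndarray]:
        return [self.gamma, self.beta]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.ggamma, self.gbeta]


class Dropout:
    """Inverted dropout: active only during training, identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask

    def penalty(self) -> float:
        return 0.0

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []


def _run(layers: Sequence, x: np.ndarray, training: bool) -> np.ndarray:
    for layer in layers:
        x = layer.forward(x, training)
    return x


def _backprop(layers: Sequence, g: np.ndarray) -> np.ndarray:
    for layer in reversed(layers):
        g = layer.backward(g)
    return g


class MLPNetwork:
    """Single-output perceptron: Dense(64, ReLU) -> Dense(32, ReLU) -> linear."""

    n_outputs = 1

    def __init__(self, n_in: int, hidden_sizes: tuple[int, int], rng: np.random.Generator) -> None:
        h1, h2 = hidden_sizes
        self.layers = [
            Dense(n_in, h1, relu=True, rng=rng),
            Dense(h1, h2, relu=True, rng=rng),
            Dense(h2, 1, rng=rng),
        ]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return _run(self.layers, x, training)

    def backward(self, g: np.ndarray) -> None:
        _backprop(self.layers, g)

    def all_layers(self) -> list:
        return list(self.layers)

    def set_output_bias(self, means: np.ndarray) -> None:
        """Start the output at the training-target mean (bias warm start)."""
        self.layers[-1].b[:] = means[:1]


class BifurcatedNetwork:
    """Shared trunk splitting into a density head and a risk head.

    Trunk: Dense(32, ReLU, L2) -> BatchNorm -> Dropout(0.4) -> Dense(8).
    Density branch: Dense(8) -> linear output.
    Risk branch: Dropout(0.3) -> linear output.
    Output columns are ordered (densitanum, riskenum).

    Only the trunk Dense(32) carries an activation; the Dense(8)
    bottleneck and the density-branch Dense(8) are linear. A linear
    bottleneck lets all eight shared units carry redundant signal, which
    is what the dropout ahead of the linear risk head punishes least:
    dropout before a linear layer acts as a ridge penalty proportional to
    sum_j w_j^2 E[z_j^2], and spreading a small-variance target (risk)
    across correlated units divides that penalty by their number. With a
    ReLU bottleneck roughly half the units are inactive per input and the
    risk head measurably loses accuracy.
    """

    n_outputs = 2

    def __init__(self, n_in: int, *, trunk_width: int = 32, bottleneck: int = 8,
                 trunk_dropout: float = 0.4, batch_norm: bool = True,
                 density_branch_width: int = 8, risk_branch_dropout: float = 0.3,
                 l2_lambda: float = 1e-3,
                 init_rng: np.random.Generator, dropout_rng: np.random.Generator) -> None:
        trunk: list = [Dense(n_in, trunk_width, relu=True, l2=l2_lambda, rng=init_rng)]
        if batch_norm:
            trunk.append(BatchNorm(trunk_width))
        trunk.append(Dropout(trunk_dropout, dropout_rng))
        trunk.append(Dense(trunk_width, bottleneck, rng=init_rng))
        self.trunk = trunk
        self.density_branch = [
            Dense(bottleneck, density_branch_width, rng=init_rng),
            Dense(density_branch_width, 1, rng=init_rng),
        ]
        self.risk_branch = [
            Dropout(risk_branch_dropout, dropout_rng),
            Dense(bottleneck, 1, rng=init_rng),
        ]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        shared = _run(self.trunk, x, training)
        dens = _run(self.density_branch, shared, training)
        risk = _run(self.risk_branch, shared, training)
        return np.concatenate([dens, risk], axis=1)

    def backward(self, g: np.ndarray) -> None:
        g_shared = _backprop(self.density_branch, g[:, [0]]) + _backprop(self.risk_branch, g[:, [1]])
        _backprop(self.trunk, g_shared)

    def all_layers(self) -> list:
        return [*self.trunk, *self.density_branch, *self.risk_branch]

    def set_output_bias(self, means: np.ndarray) -> None:
        """Start each head at its training-target mean (bias warm start)."""
        self.density_branch[-1].b[:] = means[0]
        self.risk_branch[-1].b[:] = means[1]


class Adam:
    """Adam optimizer with bias-corrected first and second moments."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _weighted_mse(pred: np.ndarray, y: np.ndarray, weights: np.ndarray) -> float:
    return float(np.sum(weights * np.mean((pred - y) ** 2, axis=0)))


def _snapshot(net) -> list[np.ndarray]:
    return [copy.deepcopy(p) for layer in net.all_layers() for p in _state(layer)]


def _restore(net, snap: list[np.ndarray]) -> None:
    i = 0
    for layer in net.all_layers():
        for p in _state(layer):
            p[...] = snap[i]
            i += 1


def _state(layer) -> list[np.ndarray]:
    # trainable parameters plus batch-norm running statistics
    extra = [layer.running_mean, layer.running_var] if isinstance(layer, BatchNorm) else []
    return [*layer.params, *extra]


def train_network(
    net,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    *,
    learning_rate: float,
    batch_size: int,
    max_epochs: int,
    patience: int,
    loss_weights: Sequence[float],
    shuffle_rng: np.random.Generator,
) -> tuple[int, list[dict[str, float]]]:
    """Mini-batch Adam training with early stopping on validation loss.

    The monitored loss is the weighted sum of per-output MSE plus the L2
    penalty (the training objective evaluated in inference mode). When no
    improvement is seen for ``patience`` consecutive epochs, training
    stops and the best-validation weights are restored. Returns the
    1-based epoch at which training stopped and the per-epoch history.
    """
    weights = np.asarray(loss_weights, dtype=float)[: net.n_outputs]
    layers = net.all_layers()
    params = [p for layer in layers for p in layer.params]
    opt = Adam(params, learning_rate)

    n = X_train.shape[0]
    best_val = np.inf
    best_snap = _snapshot(net)
    wait = 0
    stopped_epoch = max_epochs
    history: list[dict[str, float]] = []

    for epoch in range(1, max_epochs + 1):
        perm = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = perm[start : start + batch_size]
            xb, yb = X_train[idx], y_train[idx]
            pred = net.forward(xb, training=True)
            data_loss = _weighted_mse(pred, yb, weights)
            penalty = sum(layer.penalty() for layer in layers)
            epoch_loss += (data_loss + penalty) * len(idx)
            grad = 2.0 * weights * (pred - yb) / len(idx)
            net.backward(grad)
            opt.step([g for layer in layers for g in layer.grads])
        train_loss = epoch_loss / n

        val_pred = net.forward(X_val, training=False)
        val_loss = _weighted_mse(val_pred, y_val, weights) + sum(layer.penalty() for layer in layers)
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})

        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise DivergenceError(epoch)

        if val_loss < best_val:
            best_val = val_loss
            best_snap = _snapshot(net)
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                stopped_epoch = epoch
                break
    else:
        stopped_epoch = max_epochs

    _restore(net, best_snap)
    return stopped_epoch, history
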