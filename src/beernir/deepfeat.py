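"""Deep spectral feature extractors and Bayesian hyperparameter optimization.

Three architectures turn a calibration spectrum (length-P absorbance
sequence) into a d-dimensional feature vector read off the penultimate
fully-connected layer:

* ``cnn``: two 1-D convolution modules (second doubles the channel count; He
  normal initialization, same padding, ELU activations, average pooling) ->
  flatten -> FC(numResponses) -> task head.
* ``lstm``: the spectrum as a length-P sequence -> LSTM -> FC(numResponses)
  -> head.
* ``cnn_lstm``: conv modules -> sequence -> LSTM (full hidden-state
  sequence) -> multi-head self-attention (4 heads, 40-dimensional key/value
  space) -> temporal mean pool -> FC(numResponses) -> head.

Networks are trained with mini-batch Adam (shuffled batches of
``DEFAULT_BATCH_SIZE`` rows), a step-decay learning-rate schedule and an L2
penalty; the training objective is the k-fold RMSECV (regression) or ACCCV
(classification) on the calibration set. Inputs are standardized by a single
scalar mean/sd over all calibration absorbances — per-wavelength scaling
would distort the band shapes that the weight-shared convolutions rely on.
Everything is plain numpy with hand-written backward passes, so runs are
bit-reproducible under a fixed seed on one machine.

Hyperparameters are tuned by Bayesian optimization: a Gaussian-process
surrogate (Matern 5/2) with expected-improvement acquisition over a bounded
space with linear, log and integer parameter scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

ARCHS = ("cnn", "lstm", "cnn_lstm")
TASKS = ("reg_alcohol", "reg_wort", "classify")
DEFAULT_BATCH_SIZE = 8

#: attention geometry fixed by the architecture
ATTENTION_HEADS = 4
ATTENTION_KEY_DIM = 40


@dataclass(frozen=True)
class ExtractorConfig:
    """Hyperparameters of one extractor; fields irrelevant to an architecture
    (e.g. FiltSize for a pure LSTM) are simply ignored by the builder."""

    arch: str = "cnn_lstm"
    task: str = "reg_alcohol"
    numResponses: int = 32
    FiltSize: int = 7
    numChannels: int = 16
    numHiddenUnits: int = 32
    MaxEpochs: int = 60
    InitialLearnRate: float = 3e-3
    LearnRateDropPeriod: int = 100
    LearnRateDropFactor: float = 0.8
    L2Regularization: float = 1e-6

    def __post_init__(self) -> None:
        if self.arch not in ARCHS:
            raise ValueError(f"arch must be one of {ARCHS}")
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.MaxEpochs < 1:
            raise ValueError("MaxEpochs must be >= 1")
        if not (0 < self.LearnRateDropFactor < 1):
            raise ValueError("LearnRateDropFactor must be in (0, 1)")
        if self.L2Regularization < 0:
            raise ValueError("L2Regularization must be >= 0")


# ---------------------------------------------------------------------------
# layers (forward + manual backward; full-precision numpy)
# ---------------------------------------------------------------------------


class _Layer:
    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(_Layer):
    def __init__(self, d_in, d_out, rng):
        super().__init__()
        # Glorot uniform
        lim = np.sqrt(6.0 / (d_in + d_out))
        self.W = rng.uniform(-lim, lim, size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


class Conv1d(_Layer):
    """Same-padding 1-D convolution over the wavelength axis,
    (N, T, C_in) -> (N, T, C_out), He normal initialization."""

    def __init__(self, c_in, c_out, kernel, rng):
        super().__init__()
        self.k, self.c_in, self.c_out = kernel, c_in, c_out
        self.W = rng.normal(
            0.0, np.sqrt(2.0 / (kernel * c_in)), size=(kernel * c_in, c_out)
        )
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        n, t, _ = x.shape
        left = (self.k - 1) // 2
        xp = np.pad(x, ((0, 0), (left, self.k - 1 - left), (0, 0)))
        # windows: (N, T, C_in, k) -> flattened patch matrix
        pat = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        self._pat = pat.reshape(n, t, self.c_in * self.k)
        self._shape = (n, t)
        return self._pat @ self.W + self.b

    def backward(self, g):
        n, t = self._shape
        self.grads[0][...] = np.einsum("ntk,ntc->kc", self._pat, g)
        self.grads[1][...] = g.sum(axis=(0, 1))
        dpat = (g @ self.W.T).reshape(n, t, self.c_in, self.k)
        left = (self.k - 1) // 2
        dxp = np.zeros((n, t + self.k - 1, self.c_in))
        for j in range(self.k):
            dxp[:, j : j + t, :] += dpat[:, :, :, j]
        return dxp[:, left : left + t, :]


class ELU(_Layer):
    def forward(self, x, train=False):
        self._y = np.where(x > 0, x, np.expm1(x))
        return self._y

    def backward(self, g):
        return g * np.where(self._y > 0, 1.0, self._y + 1.0)


class AvgPool1d(_Layer):
    """Non-overlapping temporal average pooling; an odd trailing step is
    dropped."""

    def __init__(self, pool=2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=False):
        n, t, c = x.shape
        t2 = t // self.pool
        if t2 < 1:
            raise ValueError("pooling would reduce the sequence below length 1")
        self._t = t
        return x[:, : t2 * self.pool, :].reshape(n, t2, self.pool, c).mean(axis=2)

    def backward(self, g):
        n, t2, c = g.shape
        dx = np.zeros((n, self._t, c))
        dx[:, : t2 * self.pool, :] = np.repeat(g / self.pool, self.pool, axis=1)
        return dx


class Flatten(_Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class MeanPoolTime(_Layer):
    def forward(self, x, train=False):
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, g):
        return np.repeat(g[:, None, :] / self._t, self._t, axis=1)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTM(_Layer):
    """Single-layer LSTM returning the full hidden-state sequence or the
    final hidden state. Forget-gate bias initialized to 1."""

    def __init__(self, d_in, hidden, rng, return_sequences=True):
        super().__init__()
        self.h = hidden
        self.return_sequences = return_sequences
        lim = np.sqrt(6.0 / (d_in + 4 * hidden))
        self.Wx = rng.uniform(-lim, lim, size=(d_in, 4 * hidden))
        limh = np.sqrt(6.0 / (hidden + 4 * hidden))
        self.Wh = rng.uniform(-limh, limh, size=(hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget gate
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train=False):
        n, t, _ = x.shape
        h = self.h
        self._x = x
        self._cache = []
        h_t = np.zeros((n, h))
        c_t = np.zeros((n, h))
        out = np.empty((n, t, h))
        for s in range(t):
            z = x[:, s, :] @ self.Wx + h_t @ self.Wh + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c_prev, h_prev = c_t, h_t
            c_t = f * c_prev + i * g
            tc = np.tanh(c_t)
            h_t = o * tc
            out[:, s, :] = h_t
            self._cache.append((i, f, g, o, c_prev, h_prev, tc))
        return out if self.return_sequences else h_t

    def backward(self, grad):
        x = self._x
        n, t, _ = x.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, self.h))
        dc_next = np.zeros((n, self.h))
        for s in range(t - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, tc = self._cache[s]
            if self.return_sequences:
                dh = grad[:, s, :] + dh_next
            else:
                dh = (grad if s == t - 1 else 0.0) + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dWx += x[:, s, :].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, s, :] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
        self.grads[0][...] = dWx
        self.grads[1][...] = dWh
        self.grads[2][...] = db
        return dx


class MultiHeadSelfAttention(_Layer):
    """Scaled dot-product self-attention over the sequence axis with
    ``n_heads`` heads splitting a ``key_dim``-dimensional key/value space."""

    def __init__(self, d_model, rng, n_heads=ATTENTION_HEADS, key_dim=ATTENTION_KEY_DIM):
        super().__init__()
        if key_dim % n_heads:
            raise ValueError("key_dim must be divisible by n_heads")
        self.h = n_heads
        self.dk = key_dim // n_heads
        lim = np.sqrt(6.0 / (d_model + key_dim))
        self.Wq = rng.uniform(-lim, lim, size=(d_model, key_dim))
        self.Wk = rng.uniform(-lim, lim, size=(d_model, key_dim))
        self.Wv = rng.uniform(-lim, lim, size=(d_model, key_dim))
        limo = np.sqrt(6.0 / (key_dim + d_model))
        self.Wo = rng.uniform(-limo, limo, size=(key_dim, d_model))
        self.bo = np.zeros(d_model)
        self.params = [self.Wq, self.Wk, self.Wv, self.Wo, self.bo]
        self.grads = [np.zeros_like(p) for p in self.params]

    def _split(self, M, n, t):
        return M.reshape(n, t, self.h, self.dk).transpose(0, 2, 1, 3)

    def forward(self, x, train=False):
        n, t, _ = x.shape
        Q = self._split(x @ self.Wq, n, t)
        K = self._split(x @ self.Wk, n, t)
        V = self._split(x @ self.Wv, n, t)
        S = Q @ K.transpose(0, 1, 3, 2) / np.sqrt(self.dk)
        S -= S.max(axis=-1, keepdims=True)
        E = np.exp(S)
        A = E / E.sum(axis=-1, keepdims=True)
        O = A @ V  # (n, heads, t, dk)
        concat = O.transpose(0, 2, 1, 3).reshape(n, t, self.h * self.dk)
        self._cache = (x, Q, K, V, A, concat)
        return concat @ self.Wo + self.bo

    def backward(self, g):
        x, Q, K, V, A, concat = self._cache
        n, t, _ = x.shape
        self.grads[3][...] = np.einsum("ntk,ntd->kd", concat, g)
        self.grads[4][...] = g.sum(axis=(0, 1))
        dO = (g @ self.Wo.T).reshape(n, t, self.h, self.dk).transpose(0, 2, 1, 3)
        dA = dO @ V.transpose(0, 1, 3, 2)
        dV = A.transpose(0, 1, 3, 2) @ dO
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True)) / np.sqrt(self.dk)
        dQ = dS @ K
        dK = dS.transpose(0, 1, 3, 2) @ Q

        def merge(M):
            return M.transpose(0, 2, 1, 3).reshape(n, t, self.h * self.dk)

        dQm, dKm, dVm = merge(dQ), merge(dK), merge(dV)
        self.grads[0][...] = np.einsum("ntd,ntk->dk", x, dQm)
        self.grads[1][...] = np.einsum("ntd,ntk->dk", x, dKm)
        self.grads[2][...] = np.einsum("ntd,ntk->dk", x, dVm)
        return dQm @ self.Wq.T + dKm @ self.Wk.T + dVm @ self.Wv.T


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------


class Network:
    """Ordered layer stack with a marked feature layer (the FC whose output
    is the exported feature vector)."""

    def __init__(self, layers, feature_index, config):
        self.layers = layers
        self.feature_index = feature_index
        self.config = config

    @property
    def n_params(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def forward(self, x, return_features=False):
        feats = None
        for i, layer in enumerate(self.layers):
            x = layer.forward(x)
            if i == self.feature_index:
                feats = x
        return (x, feats) if return_features else x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)


def build_network(config: ExtractorConfig, P: int, seed: int = 0) -> Network:
    """Assemble the architecture for spectra of length P."""
    rng = np.random.default_rng(seed)
    out_dim = 3 if config.task == "classify" else 1
    layers: list[_Layer] = []
    if config.arch in ("cnn", "cnn_lstm"):
        C = config.numChannels
        layers += [
            Conv1d(1, C, config.FiltSize, rng),
            ELU(),
            AvgPool1d(2),
            Conv1d(C, 2 * C, config.FiltSize, rng),
            ELU(),
            AvgPool1d(2),
        ]
        t_out = (P // 2) // 2
        if t_out < 1:
            raise ValueError("pooling would reduce the sequence below length 1")
        if config.arch == "cnn":
            layers += [Flatten(), Dense(t_out * 2 * C, config.numResponses, rng)]
        else:
            layers += [
                LSTM(2 * C, config.numHiddenUnits, rng, return_sequences=True),
                MultiHeadSelfAttention(config.numHiddenUnits, rng),
                MeanPoolTime(),
                Dense(config.numHiddenUnits, config.numResponses, rng),
            ]
    else:  # pure lstm
        layers += [
            LSTM(1, config.numHiddenUnits, rng, return_sequences=False),
            Dense(config.numHiddenUnits, config.numResponses, rng),
        ]
    feature_index = len(layers) - 1
    layers.append(Dense(config.numResponses, out_dim, rng))
    return Network(layers, feature_index, config)


# ---------------------------------------------------------------------------
# losses and optimizer
# ---------------------------------------------------------------------------


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _loss_and_grad(out, target, task):
    n = out.shape[0]
    if task == "classify":
        p = _softmax(out)
        loss = -np.mean(np.log(np.clip(p[np.arange(n), target], 1e-12, None)))
        g = p.copy()
        g[np.arange(n), target] -= 1.0
        return float(loss), g / n
    resid = out.ravel() - target
    return float(np.mean(resid**2)), (2.0 * resid / n)[:, None]


class _Adam:
    def __init__(self, net, lr, l2, drop_period, drop_factor):
        self.net = net
        self.lr0, self.l2 = lr, l2
        self.drop_period, self.drop_factor = drop_period, drop_factor
        self.m = [np.zeros_like(p) for p, _ in net.parameters()]
        self.v = [np.zeros_like(p) for p, _ in net.parameters()]
        self.t = 0

    def step(self, epoch):
        lr = self.lr0 * self.drop_factor ** (epoch // max(1, self.drop_period))
        self.t += 1
        # global-norm gradient clipping keeps early steps stable
        gsq = sum(float(np.sum(g**2)) for _, g in self.net.parameters())
        scale = min(1.0, 5.0 / (np.sqrt(gsq) + 1e-12))
        for k, (p, g) in enumerate(self.net.parameters()):
            grad = g * scale
            if p.ndim > 1 and self.l2 > 0:  # weight matrices only
                grad = grad + self.l2 * p
            self.m[k] = 0.9 * self.m[k] + 0.1 * grad
            self.v[k] = 0.999 * self.v[k] + 0.001 * grad**2
            mhat = self.m[k] / (1 - 0.9**self.t)
            vhat = self.v[k] / (1 - 0.999**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + 1e-8)


def _fit_network(config, X3, target, seed, batch_size=DEFAULT_BATCH_SIZE):
    net = build_network(config, X3.shape[1], seed=seed)
    opt = _Adam(
        net,
        config.InitialLearnRate,
        config.L2Regularization,
        config.LearnRateDropPeriod,
        config.LearnRateDropFactor,
    )
    rng = np.random.default_rng(seed + 7919)
    n = X3.shape[0]
    batch_size = min(batch_size, n)
    for epoch in range(config.MaxEpochs):
        perm = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = perm[start : start + batch_size]
            out = net.forward(X3[idx])
            loss, g = _loss_and_grad(out, target[idx], config.task)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (non-finite loss) for {config}")
            net.backward(g)
            opt.step(epoch)
    return net


# ---------------------------------------------------------------------------
# trained extractor
# ---------------------------------------------------------------------------


@dataclass
class TrainedExtractor:
    net: Network
    config: ExtractorConfig
    n_wavelengths: int
    x_mean: float  # scalar standardization preserves spectral band shape
    x_sd: float
    y_mean: float = 0.0
    y_sd: float = 1.0
    classes: np.ndarray | None = None

    def _prep(self, X):
        X = np.asarray(X, float)
        if X.shape[1] != self.n_wavelengths:
            raise ValueError(
                f"input has {X.shape[1]} wavelengths, model expects {self.n_wavelengths}"
            )
        return ((X - self.x_mean) / self.x_sd)[:, :, None]

    def predict(self, X):
        out = self.net.forward(self._prep(X))
        if self.config.task == "classify":
            return self.classes[np.argmax(out, axis=1)]
        return out.ravel() * self.y_sd + self.y_mean

    def predict_proba(self, X):
        if self.config.task != "classify":
            raise ValueError("probabilities only defined for the classification head")
        return _softmax(self.net.forward(self._prep(X)))


def extract_features(model: TrainedExtractor, X: np.ndarray) -> np.ndarray:
    """Penultimate fully-connected activations, (N, numResponses)."""
    _, feats = model.net.forward(model._prep(X), return_features=True)
    return feats


def train_extractor(
    config: ExtractorConfig,
    X_cal: np.ndarray,
    y_or_labels: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    batch_size: int = DEFAULT_BATCH_SIZE,
) -> tuple[TrainedExtractor, float]:
    """k-fold training loop returning (model refit on all calibration rows,
    objective). The objective is RMSECV pooled over held-out folds for
    regression tasks and pooled held-out accuracy (ACCCV, %) for
    classification."""
    X = np.asarray(X_cal, float)
    n, _ = X.shape
    if folds > n:
        raise ValueError("fold count exceeds sample count")
    is_class = config.task == "classify"
    classes = np.unique(y_or_labels) if is_class else None
    perm = np.random.default_rng(seed).permutation(n)
    fold_of = np.empty(n, int)
    fold_of[perm] = np.arange(n) % folds
    pooled_pred = np.empty(n, dtype=object if is_class else float)
    for f in range(folds):
        tr = np.flatnonzero(fold_of != f)
        te = np.flatnonzero(fold_of == f)
        xm, xs = float(X[tr].mean()), float(max(X[tr].std(), 1e-12))
        X3 = ((X[tr] - xm) / xs)[:, :, None]
        if is_class:
            target = np.searchsorted(classes, y_or_labels[tr])
        else:
            y = np.asarray(y_or_labels, float)
            ym, ys = y[tr].mean(), max(y[tr].std(), 1e-12)
            target = (y[tr] - ym) / ys
        net = _fit_network(config, X3, target, seed=seed + 101 * f, batch_size=batch_size)
        out = net.forward(((X[te] - xm) / xs)[:, :, None])
        if is_class:
            pooled_pred[te] = classes[np.argmax(out, axis=1)]
        else:
            pooled_pred[te] = out.ravel() * ys + ym
    if is_class:
        objective = 100.0 * float(np.mean(pooled_pred == np.asarray(y_or_labels)))
    else:
        y = np.asarray(y_or_labels, float)
        objective = float(np.sqrt(np.mean((pooled_pred.astype(float) - y) ** 2)))
    # final refit on all calibration rows
    xm, xs = float(X.mean()), float(max(X.std(), 1e-12))
    if is_class:
        target = np.searchsorted(classes, np.asarray(y_or_labels))
        ym, ys = 0.0, 1.0
    else:
        y = np.asarray(y_or_labels, float)
        ym, ys = float(y.mean()), float(max(y.std(), 1e-12))
        target = (y - ym) / ys
    net = _fit_network(
        config, ((X - xm) / xs)[:, :, None], target, seed=seed, batch_size=batch_size
    )
    model = TrainedExtractor(
        net=net,
        config=config,
        n_wavelengths=X.shape[1],
        x_mean=xm,
        x_sd=xs,
        y_mean=ym,
        y_sd=ys,
        classes=classes,
    )
    return model, objective


# ---------------------------------------------------------------------------
# Bayesian optimization (GP surrogate + expected improvement)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BOAParam:
    low: float
    high: float
    scale: str = "linear"  # linear | log | integer

    def __post_init__(self) -> None:
        if not (self.low < self.high):
            raise ValueError("require low < high")
        if self.scale not in ("linear", "log", "integer"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "log" and self.low <= 0:
            raise ValueError("log-scaled bounds must be positive")

    def from_unit(self, u: float):
        if self.scale == "log":
            return float(
                np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low)))
            )
        v = self.low + u * (self.high - self.low)
        return int(round(v)) if self.scale == "integer" else float(v)


@dataclass
class BOAResult:
    best_params: dict
    best_objective: float
    trace: np.ndarray  # running incumbent objective per evaluation
    evaluations: pd.DataFrame


def boa_optimize(
    space: dict[str, BOAParam],
    objective_fn,
    n_iter: int = 20,
    n_init: int = 5,
    seed: int = 0,
    maximize: bool = False,
) -> BOAResult:
    """Sequential GP/EI optimization over the unit cube.

    ``objective_fn`` receives a dict of parameter values; a non-finite
    return is recorded as a failed point and excluded from the surrogate.
    The trace is the running incumbent, monotone under the optimization
    direction; its length equals ``n_iter`` total evaluations (including
    the ``n_init`` seeding draws)."""
    if not space:
        raise ValueError("empty search space")
    if not (1 <= n_init <= n_iter):
        raise ValueError("require 1 <= n_init <= n_iter")
    names = list(space)
    d = len(names)
    rng = np.random.default_rng(seed)
    sign = -1.0 if maximize else 1.0
    U, vals, records = [], [], []

    def evaluate(u):
        params = {nm: space[nm].from_unit(float(ui)) for nm, ui in zip(names, u)}
        val = objective_fn(params)
        val = float(val) if val is not None and np.isfinite(val) else np.nan
        U.append(np.asarray(u, float))
        vals.append(val)
        records.append({**params, "objective": val})

    for _ in range(n_init):
        evaluate(rng.uniform(size=d))
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(d, 0.3), length_scale_bounds=(1e-2, 1e2), nu=2.5
    )
    while len(vals) < n_iter:
        finite = [i for i, v in enumerate(vals) if np.isfinite(v)]
        if len(finite) < 2:
            evaluate(rng.uniform(size=d))
            continue
        Xg = np.vstack([U[i] for i in finite])
        yg = sign * np.array([vals[i] for i in finite])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp = GaussianProcessRegressor(
                kernel=kernel, alpha=1e-6, normalize_y=True, random_state=seed
            ).fit(Xg, yg)
        cand = rng.uniform(size=(256, d))
        mu, sd = gp.predict(cand, return_std=True)
        sd = np.maximum(sd, 1e-12)
        imp = yg.min() - mu - 0.01
        z = imp / sd
        ei = imp * norm.cdf(z) + sd * norm.pdf(z)
        evaluate(cand[int(np.argmax(ei))])
    signed = np.array([sign * v if np.isfinite(v) else np.inf for v in vals])
    trace = np.minimum.accumulate(signed) * sign
    best_i = int(np.argmin(signed))
    best_params = {nm: space[nm].from_unit(float(ui)) for nm, ui in zip(names, U[best_i])}
    return BOAResult(
        best_params=best_params,
        best_objective=float(vals[best_i]),
        trace=trace,
        evaluations=pd.DataFrame(records),
    )


def default_space(arch: str) -> dict[str, BOAParam]:
    """Bounds bracketing every published optimum for each architecture."""
    space = {
        "numResponses": BOAParam(16, 128, "integer"),
        "MaxEpochs": BOAParam(50, 400, "integer"),
        "InitialLearnRate": BOAParam(1e-4, 1e-2, "log"),
        "LearnRateDropPeriod": BOAParam(50, 150, "integer"),
        "LearnRateDropFactor": BOAParam(0.4, 0.95, "linear"),
        "L2Regularization": BOAParam(1e-10, 1e-2, "log"),
    }
    if arch in ("cnn", "cnn_lstm"):
        space["FiltSize"] = BOAParam(3, 15, "integer")
        space["numChannels"] = BOAParam(8, 64, "integer")
    if arch in ("lstm", "cnn_lstm"):
        space["numHiddenUnits"] = BOAParam(16, 128, "integer")
    return space


def tune_extractor(
    arch: str,
    task: str,
    X_cal: np.ndarray,
    y_or_labels: np.ndarray,
    n_iter: int = 20,
    n_init: int = 5,
    folds: int = 5,
    seed: int = 0,
    max_epochs_cap: int | None = 60,
    max_channels_cap: int | None = None,
    max_hidden_cap: int | None = None,
    space: dict | None = None,
) -> tuple[TrainedExtractor, float, BOAResult]:
    """BOA-tune an extractor on calibration data, then train the best config.

    ``max_epochs_cap`` (and optionally ``max_channels_cap`` /
    ``max_hidden_cap``) shrink the search space for desk-scale runs; pass
    None to search the full bounds.
    """
    space = dict(space if space is not None else default_space(arch))
    if max_epochs_cap is not None and "MaxEpochs" in space:
        space["MaxEpochs"] = BOAParam(
            min(20, max_epochs_cap - 1), max_epochs_cap, "integer"
        )
    if max_channels_cap is not None and "numChannels" in space:
        space["numChannels"] = BOAParam(
            min(4, max_channels_cap - 1), max_channels_cap, "integer"
        )
    if max_hidden_cap is not None and "numHiddenUnits" in space:
        space["numHiddenUnits"] = BOAParam(
            min(16, max_hidden_cap - 1), max_hidden_cap, "integer"
        )
    maximize = task == "classify"

    def objective_fn(params):
        cfg = ExtractorConfig(arch=arch, task=task, **params)
        try:
            _, obj = train_extractor(cfg, X_cal, y_or_labels, folds=folds, seed=seed)
        except RuntimeError:
            return np.nan
        return obj

    result = boa_optimize(
        space, objective_fn, n_iter=n_iter, n_init=n_init, seed=seed, maximize=maximize
    )
    cfg = ExtractorConfig(arch=arch, task=task, **result.best_params)
    model, objective = train_extractor(cfg, X_cal, y_or_labels, folds=folds, seed=seed)
    return model, objective, result
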