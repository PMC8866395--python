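"""Deep binary classifiers: dense feedforward net, bidirectional LSTM, and
a BrainNetCNN-style connectivity network, trained with Adam on a
binary-cross-entropy-with-logits loss plus L2 weight decay.

All three expose the same surface: ``fit(X, y, validation=...)`` with
optional early stopping, ``decision_function(X)`` returning logits, and
``fine_tune`` for warm-start supervised domain adaptation. Training is
deterministic given the construction seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["TrainingOptions", "DFNNClassifier", "BiLSTMClassifier",
           "BrainNetCNNClassifier"]


@dataclass
class TrainingOptions:
    """Optimization defaults shared by the deep families.

    epochs is a budget; with a validation set, early stopping (patience in
    epochs, best weights restored) usually halts sooner.
    """

    epochs: int = 120
    batch_size: int = 32
    lr: float = 1e-3
    patience: int = 15
    min_delta: float = 1e-5


class _Adam:
    def __init__(self, params: list[Tensor], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def _bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    # mean(softplus(z) - z*y): numerically stable binary cross-entropy
    return (ag.softplus(logits) - logits * Tensor(y)).mean()


class _BaseNet:
    """Shared training loop; subclasses define parameters and `_forward`."""

    def __init__(self, l2: float, seed: int, options: TrainingOptions | None):
        self.l2 = float(l2)
        self.seed = int(seed)
        self.options = options or TrainingOptions()
        self.params: list[Tensor] = []
        self.weight_params: list[Tensor] = []   # L2 applies to these only
        self.fitted_ = False

    # subclass API -----------------------------------------------------------
    def _forward(self, X: np.ndarray, train: bool, rng) -> Tensor:  # pragma: no cover
        raise NotImplementedError

    # weights ----------------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p.data = w.copy()

    def clone(self):
        return copy.deepcopy(self)

    # training ----------------------------------------------------------------
    def _loss(self, X, y, train, rng) -> Tensor:
        logits = self._forward(X, train=train, rng=rng)
        loss = _bce_with_logits(logits, y)
        if self.l2 > 0:
            penalty = None
            for W in self.weight_params:
                term = (W * W).sum()
                penalty = term if penalty is None else penalty + term
            loss = loss + self.l2 * penalty
        return loss

    def _run_training(self, X, y, validation, epochs, lr, rng) -> None:
        opts = self.options
        opt = _Adam(self.params, lr=lr)
        best_loss, best_weights, since_best = np.inf, None, 0
        n = X.shape[0]
        for _epoch in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, opts.batch_size):
                idx = order[start:start + opts.batch_size]
                opt.zero_grad()
                loss = self._loss(X[idx], y[idx], train=True, rng=rng)
                loss.backward()
                opt.step()
            if validation is not None:
                Xv, yv = validation
                val_loss = float(self._loss(Xv, yv, train=False, rng=rng).data)
                if val_loss < best_loss - opts.min_delta:
                    best_loss, best_weights, since_best = val_loss, self.get_weights(), 0
                else:
                    since_best += 1
                    if since_best >= opts.patience:
                        break
        if validation is not None and best_weights is not None:
            self.set_weights(best_weights)

    def fit(self, X, y, validation=None):
        """Train from the seeded initialization.

        validation: optional (X_val, y_val) monitored for early stopping
        (best validation loss restored).
        """
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 1]))
        self._run_training(X, y, validation, self.options.epochs, self.options.lr, rng)
        self.fitted_ = True
        return self

    def fine_tune(self, X, y, validation=None, epochs: int | None = None,
                  lr: float | None = None, seed: int | None = None):
        """Continue training from the current weights (domain adaptation).

        epochs=0 leaves the model unchanged. The learning rate defaults to
        the training rate; with a warm start, regularization comes from
        early stopping rather than a reduced step size.
        """
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        epochs = self.options.epochs if epochs is None else int(epochs)
        if epochs == 0:
            return self
        lr = self.options.lr if lr is None else lr
        rng = np.random.default_rng(np.random.SeedSequence(
            [self.seed if seed is None else int(seed), 2]))
        self._run_training(X, y, validation, epochs, lr, rng)
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        logits = self._forward(X, train=False, rng=None)
        return logits.data.reshape(-1)


def _he_init(rng, fan_in, shape):
    return rng.standard_normal(shape) * np.sqrt(2.0 / max(fan_in, 1))


def _dropout(t: Tensor, p: float, train: bool, rng) -> Tensor:
    if not train or p <= 0:
        return t
    mask = (rng.random(t.data.shape) >= p) / (1.0 - p)
    return t * Tensor(mask)


class DFNNClassifier(_BaseNet):
    """Dense feedforward network: tapering hidden stack, 1-unit decision layer.

    Hidden layer l has width ``max(8, initial_width // 2**l)`` (the first
    layer gets the full initial width), ReLU activations, dropout after
    every hidden layer.
    """

    def __init__(self, n_features: int, hidden_layers: int = 2, initial_width: int = 64,
                 dropout: float = 0.2, l2: float = 1e-4, seed: int = 0,
                 options: TrainingOptions | None = None):
        super().__init__(l2, seed, options)
        if hidden_layers < 1:
            raise ValueError("hidden_layers must be >= 1")
        self.dropout = float(dropout)
        self.widths = [max(8, initial_width // (2 ** l)) for l in range(hidden_layers)]
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        dims = [n_features] + self.widths + [1]
        self.Ws, self.bs = [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            W = Tensor(_he_init(rng, d_in, (d_in, d_out)))
            b = Tensor(np.zeros(d_out))
            self.Ws.append(W)
            self.bs.append(b)
            self.params += [W, b]
            self.weight_params.append(W)

    def _forward(self, X, train, rng):
        h = Tensor(X)
        for W, b in zip(self.Ws[:-1], self.bs[:-1]):
            h = ag.relu(h @ W + b)
            h = _dropout(h, self.dropout, train, rng)
        return h @ self.Ws[-1] + self.bs[-1]


class BiLSTMClassifier(_BaseNet):
    """Bidirectional LSTM over a chunked feature vector, dense head on top.

    Fixed-length feature vectors are zero-padded and reshaped into
    ``n_chunks`` equal-length steps (the sequence axis is synthetic, matching
    the practice of running recurrent models on non-sequential vectors).
    Final forward and backward hidden states are concatenated and passed to
    a tapering dense stack of ``hidden_layers`` layers.
    """

    def __init__(self, n_features: int, hidden_layers: int = 1, initial_width: int = 32,
                 dropout: float = 0.2, l2: float = 1e-4, seed: int = 0,
                 n_chunks: int = 8, options: TrainingOptions | None = None):
        super().__init__(l2, seed, options)
        self.n_features = n_features
        self.n_chunks = int(n_chunks)
        self.chunk = int(np.ceil(n_features / self.n_chunks))
        self.pad = self.chunk * self.n_chunks - n_features
        self.hidden = max(8, initial_width // 2)    # per direction
        self.dropout = float(dropout)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        h, d = self.hidden, self.chunk
        self.cells = []
        for _direction in range(2):
            Wx = Tensor(_he_init(rng, d, (d, 4 * h)))
            Wh = Tensor(_he_init(rng, h, (h, 4 * h)))
            b = Tensor(np.zeros(4 * h))
            self.cells.append((Wx, Wh, b))
            self.params += [Wx, Wh, b]
            self.weight_params += [Wx, Wh]
        widths = [max(8, initial_width // (2 ** l)) for l in range(hidden_layers)]
        dims = [2 * h] + widths + [1]
        self.Ws, self.bs = [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            W = Tensor(_he_init(rng, d_in, (d_in, d_out)))
            b = Tensor(np.zeros(d_out))
            self.Ws.append(W)
            self.bs.append(b)
            self.params += [W, b]
            self.weight_params.append(W)

    def _sequence(self, X: np.ndarray) -> np.ndarray:
        if self.pad:
            X = np.pad(X, [(0, 0), (0, self.pad)])
        return X.reshape(X.shape[0], self.n_chunks, self.chunk)

    def _run_direction(self, seq: np.ndarray, cell, reverse: bool) -> Tensor:
        Wx, Wh, b = cell
        n, h = seq.shape[0], self.hidden
        hs = Tensor(np.zeros((n, h)))
        cs = Tensor(np.zeros((n, h)))
        steps = range(self.n_chunks - 1, -1, -1) if reverse else range(self.n_chunks)
        for t in steps:
            gates = Tensor(seq[:, t, :]) @ Wx + hs @ Wh + b
            i = ag.sigmoid(ag.narrow(gates, 0, h))
            f = ag.sigmoid(ag.narrow(gates, h, h))
            g = ag.tanh(ag.narrow(gates, 2 * h, h))
            o = ag.sigmoid(ag.narrow(gates, 3 * h, h))
            cs = f * cs + i * g
            hs = o * ag.tanh(cs)
        return hs

    def _forward(self, X, train, rng):
        seq = self._sequence(np.asarray(X, float))
        fwd = self._run_direction(seq, self.cells[0], reverse=False)
        bwd = self._run_direction(seq, self.cells[1], reverse=True)
        h = ag.concat([fwd, bwd], axis=1)
        h = _dropout(h, self.dropout, train, rng)
        for W, b in zip(self.Ws[:-1], self.bs[:-1]):
            h = ag.relu(h @ W + b)
            h = _dropout(h, self.dropout, train, rng)
        return h @ self.Ws[-1] + self.bs[-1]


class BrainNetCNNClassifier(_BaseNet):
    """Connectivity CNN: edge-to-edge blocks, edge-to-node, node-to-graph.

    Operates on square symmetric connectivity matrices only. hidden_layers
    (0-2) counts the edge-to-edge blocks; `width` is the number of feature
    maps; leaky-ReLU activations with a configurable negative slope.
    Covariate columns, if supplied, join at the final dense layer.
    """

    def __init__(self, n_rois: int, n_covariates: int = 0, hidden_layers: int = 1,
                 initial_width: int = 16, dropout: float = 0.2,
                 leaky_slope: float = 0.2, l2: float = 0.0, seed: int = 0,
                 options: TrainingOptions | None = None):
        super().__init__(l2, seed, options)
        if hidden_layers < 0:
            raise ValueError("hidden_layers must be >= 0")
        self.n_rois = int(n_rois)
        self.n_covariates = int(n_covariates)
        self.slope = float(leaky_slope)
        self.dropout = float(dropout)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        R, C = self.n_rois, int(initial_width)
        self.e2e_filters = []
        c_in = 1
        for _l in range(hidden_layers):
            r = Tensor(rng.standard_normal((C, c_in, R)) * np.sqrt(1.0 / (c_in * R)))
            s = Tensor(rng.standard_normal((C, c_in, R)) * np.sqrt(1.0 / (c_in * R)))
            self.e2e_filters.append((r, s))
            self.params += [r, s]
            self.weight_params += [r, s]
            c_in = C
        self.e2n_w = Tensor(rng.standard_normal((c_in, R)) * np.sqrt(1.0 / R))
        self.n2g_v = Tensor(rng.standard_normal((c_in, R)) * np.sqrt(1.0 / R))
        self.params += [self.e2n_w, self.n2g_v]
        self.weight_params += [self.e2n_w, self.n2g_v]
        d_in = c_in + self.n_covariates
        self.W_out = Tensor(_he_init(rng, d_in, (d_in, 1)))
        self.b_out = Tensor(np.zeros(1))
        self.params += [self.W_out, self.b_out]
        self.weight_params.append(self.W_out)

    def _forward(self, X, train, rng):
        # X packs [flattened R*R matrix | covariates] per row
        X = np.asarray(X, float)
        R = self.n_rois
        mats = X[:, :R * R].reshape(-1, 1, R, R)
        cov = X[:, R * R:]
        A = Tensor(mats)
        for r, s in self.e2e_filters:
            A = ag.leaky_relu(ag.e2e(A, r, s), self.slope)
        H = ag.leaky_relu(ag.e2n(A, self.e2n_w), self.slope)
        g = ag.leaky_relu(ag.n2g(H, self.n2g_v), self.slope)
        g = _dropout(g, self.dropout, train, rng)
        if self.n_covariates:
            g = ag.concat([g, Tensor(cov)], axis=1)
        return g @ self.W_out + self.b_out

    @staticmethod
    def pack_input(matrices: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
        """Flatten (N, R, R) matrices and append covariates column-wise."""
        flat = matrices.reshape(matrices.shape[0], -1)
        if covariates is None or covariates.size == 0:
            return flat
        return np.hstack([flat, covariates])
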