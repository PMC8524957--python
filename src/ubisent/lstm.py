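"""Gated recurrent (LSTM) sentence classifier.

The classifier encodes the 500-dimensional sentence representation with a
two-layer LSTM (hidden width equal to the input width, hidden and cell
states initialized to zero) and maps the final hidden state through a
linear two-class head.  The cell follows the standard gate equations

    i_t = sigmoid(W_i [x_t, h_{t-1}] + b_i)      (input gate)
    f_t = sigmoid(W_f [x_t, h_{t-1}] + b_f)      (forget gate)
    o_t = sigmoid(W_o [x_t, h_{t-1}] + b_o)      (output gate)
    v_t = tanh   (W_v [x_t, h_{t-1}] + b_v)      (candidate)
    c_t = f_t * c_{t-1} + i_t * v_t
    h_t = o_t * tanh(c_t)

Training minimizes softmax cross-entropy with a gradient-descent
optimizer (Adam by default, plain SGD by flag) at learning rate 0.001.
Two input layouts are supported: ``single_step`` feeds the whole
representation as one timestep of width t = 500 (the default), and
``per_dimension`` feeds the t components as t scalar timesteps.

Everything — forward pass, backpropagation through time, Adam — is
implemented in NumPy, so training is deterministic given the seed.
:class:`LSTMSentenceClassifier` is a scikit-learn compatible estimator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = ["LSTMConfig", "LSTMSentenceClassifier", "lstm_cell_step", "train", "predict"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def lstm_cell_step(
    x: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    weights: Mapping[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update: returns (h_t, c_t).

    ``weights`` holds ``W_x`` (4H x D), ``W_h`` (4H x H) and ``b`` (4H,),
    with the four gate blocks stacked in the order input gate, forget
    gate, candidate, output gate.  Inputs may be single vectors or
    batches (rows).
    """
    W_x, W_h, b = weights["W_x"], weights["W_h"], weights["b"]
    H = W_h.shape[1]
    if W_x.shape[0] != 4 * H or b.shape[0] != 4 * H:
        raise ValueError("inconsistent gate weight shapes")
    squeeze = x.ndim == 1
    x2 = np.atleast_2d(x)
    h2 = np.atleast_2d(h_prev)
    c2 = np.atleast_2d(c_prev)
    if x2.shape[1] != W_x.shape[1] or h2.shape[1] != H or c2.shape[1] != H:
        raise ValueError("input/state dimensions do not match the weights")
    z = x2 @ W_x.T + h2 @ W_h.T + b
    i = _sigmoid(z[:, 0 * H : 1 * H])
    f = _sigmoid(z[:, 1 * H : 2 * H])
    v = np.tanh(z[:, 2 * H : 3 * H])
    o = _sigmoid(z[:, 3 * H : 4 * H])
    c = f * c2 + i * v
    h = o * np.tanh(c)
    if squeeze:
        return h[0], c[0]
    return h, c


@dataclass
class LSTMConfig:
    """Training configuration; hidden width defaults to the input width."""

    input_size: int = 500
    hidden_size: int = 500
    num_layers: int = 2
    learning_rate: float = 0.001
    epochs: int = 10
    batch_size: int = 32
    optimizer_name: str = "adam"
    seed: int = 0
    input_mode: str = "single_step"  # or "per_dimension"


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class _SGD:
    def __init__(self, params: dict[str, np.ndarray], lr: float) -> None:
        self.lr = lr

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            params[k] -= self.lr * g


class LSTMSentenceClassifier(BaseEstimator, ClassifierMixin):
    """Two-layer LSTM + linear head binary classifier (NumPy, CPU).

    Parameters
    ----------
    hidden_size : int
        Cells per hidden layer; ``None`` means "match the input width",
        reproducing the default 500-wide configuration for 500-dim input.
    num_layers : int
        Stacked LSTM layers (default 2).
    learning_rate : float
        Step size for the optimizer (default 0.001).
    epochs : int
        Complete passes over the training set.
    batch_size : int
        Minibatch size for gradient updates.
    optimizer : {"adam", "sgd"}
        Gradient-descent update rule.
    seed : int
        Controls weight initialization and minibatch shuffling.
    input_mode : {"single_step", "per_dimension"}
        Whole vector as one timestep, or one scalar timestep per
        component.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Class labels (0 = negative, 1 = positive).
    params_ : dict
        Learned weights.
    loss_curve_ : list of float
        Mean cross-entropy per epoch.
    """

    def __init__(
        self,
        hidden_size: int | None = None,
        num_layers: int = 2,
        learning_rate: float = 0.001,
        epochs: int = 10,
        batch_size: int = 32,
        optimizer: str = "adam",
        seed: int = 0,
        input_mode: str = "single_step",
    ) -> None:
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.seed = seed
        self.input_mode = input_mode

    # -- construction -------------------------------------------------

    def _init_params(self, input_size: int, hidden: int, rng: np.random.Generator) -> dict:
        params: dict[str, np.ndarray] = {}
        bound = 1.0 / np.sqrt(hidden)
        for layer in range(self.num_layers):
            d_in = input_size if layer == 0 else hidden
            params[f"W_x{layer}"] = rng.uniform(-bound, bound, size=(4 * hidden, d_in))
            params[f"W_h{layer}"] = rng.uniform(-bound, bound, size=(4 * hidden, hidden))
            params[f"b{layer}"] = rng.uniform(-bound, bound, size=4 * hidden)
        params["W_out"] = rng.uniform(-bound, bound, size=(2, hidden))
        params["b_out"] = rng.uniform(-bound, bound, size=2)
        return params

    def _sequence(self, X: np.ndarray) -> np.ndarray:
        """Reshape (n, d) into (n, T, input_size) per the input mode."""
        if self.input_mode == "single_step":
            return X[:, None, :]
        if self.input_mode == "per_dimension":
            return X[:, :, None]
        raise ValueError(f"unknown input_mode {self.input_mode!r}")

    def initial_state(self) -> tuple[np.ndarray, np.ndarray]:
        """Zero (hidden, cell) states of shape (num_layers, hidden_size)."""
        h = np.zeros((self.num_layers, self.hidden_size_))
        return h, h.copy()

    # -- forward / backward -------------------------------------------

    def _forward(self, seq: np.ndarray, cache: bool = False):
        """Run the stacked LSTM over (B, T, D) input; return logits [+ cache]."""
        B, T, _ = seq.shape
        H = self.hidden_size_
        p = self.params_
        h = [np.zeros((B, H)) for _ in range(self.num_layers)]
        c = [np.zeros((B, H)) for _ in range(self.num_layers)]
        caches = []
        for t in range(T):
            x = seq[:, t, :]
            step_caches = []
            for layer in range(self.num_layers):
                W_x, W_h, b = p[f"W_x{layer}"], p[f"W_h{layer}"], p[f"b{layer}"]
                z = x @ W_x.T + h[layer] @ W_h.T + b
                i = _sigmoid(z[:, 0 * H : 1 * H])
                f = _sigmoid(z[:, 1 * H : 2 * H])
                v = np.tanh(z[:, 2 * H : 3 * H])
                o = _sigmoid(z[:, 3 * H : 4 * H])
                c_new = f * c[layer] + i * v
                tanh_c = np.tanh(c_new)
                h_new = o * tanh_c
                if cache:
                    step_caches.append((x, h[layer], c[layer], i, f, v, o, c_new, tanh_c))
                h[layer], c[layer] = h_new, c_new
                x = h_new
            if cache:
                caches.append(step_caches)
        logits = h[-1] @ p["W_out"].T + p["b_out"]
        if cache:
            return logits, h[-1], caches
        return logits

    def _backward(self, seq, logits, h_top, caches, y) -> dict[str, np.ndarray]:
        B, T, _ = seq.shape
        H = self.hidden_size_
        p = self.params_
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        probs = _softmax(logits)
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads["W_out"] = dlogits.T @ h_top
        grads["b_out"] = dlogits.sum(axis=0)
        dh_next = [np.zeros((B, H)) for _ in range(self.num_layers)]
        dc_next = [np.zeros((B, H)) for _ in range(self.num_layers)]
        dh_next[-1] = dlogits @ p["W_out"]
        for t in range(T - 1, -1, -1):
            dx_from_above = None
            for layer in range(self.num_layers - 1, -1, -1):
                x, h_prev, c_prev, i, f, v, o, c_new, tanh_c = caches[t][layer]
                dh = dh_next[layer].copy()
                if dx_from_above is not None:
                    dh += dx_from_above
                dc = dc_next[layer] + dh * o * (1.0 - tanh_c**2)
                do = dh * tanh_c
                di = dc * v
                df = dc * c_prev
                dv = dc * i
                dz = np.concatenate(
                    [
                        di * i * (1.0 - i),
                        df * f * (1.0 - f),
                        dv * (1.0 - v**2),
                        do * o * (1.0 - o),
                    ],
                    axis=1,
                )
                grads[f"W_x{layer}"] += dz.T @ x
                grads[f"W_h{layer}"] += dz.T @ h_prev
                grads[f"b{layer}"] += dz.sum(axis=0)
                dx_from_above = dz @ p[f"W_x{layer}"]
                dh_next[layer] = dz @ p[f"W_h{layer}"]
                dc_next[layer] = dc * f
        return grads

    # -- sklearn API ---------------------------------------------------

    def fit(self, X, y) -> "LSTMSentenceClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_features) aligned with y")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training set must contain both classes")
        if not np.isin(classes, [0, 1]).all():
            raise ValueError("labels must be 0 (negative) / 1 (positive)")
        self.classes_ = np.array([0, 1])
        n, d = X.shape
        self.input_size_ = d if self.input_mode == "single_step" else 1
        self.hidden_size_ = self.hidden_size if self.hidden_size is not None else d
        rng = np.random.default_rng(self.seed)
        self.params_ = self._init_params(self.input_size_, self.hidden_size_, rng)
        if self.optimizer == "adam":
            opt = _Adam(self.params_, self.learning_rate)
        elif self.optimizer == "sgd":
            opt = _SGD(self.params_, self.learning_rate)
        else:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        self.loss_curve_ = []
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            total_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                seq = self._sequence(X[idx])
                logits, h_top, caches = self._forward(seq, cache=True)
                probs = _softmax(logits)
                eps = 1e-12
                loss = -np.log(probs[np.arange(len(idx)), y[idx]] + eps).mean()
                total_loss += loss * len(idx)
                grads = self._backward(seq, logits, h_top, caches, y[idx])
                opt.step(self.params_, grads)
            self.loss_curve_.append(total_loss / n)
        return self

    def decision_scores(self, X) -> np.ndarray:
        """Raw 2-class scores of the linear head, shape (n, 2)."""
        if not hasattr(self, "params_"):
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        logits = self._forward(self._sequence(X))
        return logits[0] if single else logits

    def predict_proba(self, X) -> np.ndarray:
        return _softmax(np.atleast_2d(self.decision_scores(X)))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # Ties resolve to the negative class.
        return (proba[:, 1] > proba[:, 0]).astype(np.int64)

    # -- persistence ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize config + weights to an .npz archive."""
        if not hasattr(self, "params_"):
            raise RuntimeError("nothing to save: classifier is not fitted")
        meta = {
            "get_params": self.get_params(),
            "input_size_": self.input_size_,
            "hidden_size_": self.hidden_size_,
            "loss_curve_": list(self.loss_curve_),
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8),
            **self.params_,
        )

    @classmethod
    def load(cls, path: str | Path) -> "LSTMSentenceClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
            model = cls(**meta["get_params"])
            model.input_size_ = meta["input_size_"]
            model.hidden_size_ = meta["hidden_size_"]
            model.loss_curve_ = meta["loss_curve_"]
            model.classes_ = np.array([0, 1])
            model.params_ = {k: data[k].copy() for k in data.files if k != "__meta__"}
        return model


# ---------------------------------------------------------------------------
# Thin functional wrappers


def train(X, y, config: LSTMConfig | None = None) -> LSTMSentenceClassifier:
    """Train an :class:`LSTMSentenceClassifier` from an :class:`LSTMConfig`."""
    config = config or LSTMConfig()
    model = LSTMSentenceClassifier(
        hidden_size=config.hidden_size,
        num_layers=config.num_layers,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        optimizer=config.optimizer_name,
        seed=config.seed,
        input_mode=config.input_mode,
    )
    return model.fit(X, y)


def predict(model: LSTMSentenceClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """(labels, class probabilities) for a fitted model."""
    proba = model.predict_proba(X)
    labels = model.predict(X)
    return labels, proba
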