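"""A compact LSTM sequence classifier in pure numpy.

One recurrent layer (default 100 units) reads a left-padded, masked
sequence of embedding+time-channel vectors; the final hidden state,
concatenated with per-patient demographics, feeds a linear output head —
softmax with categorical cross-entropy for 3-way multiclass prediction, or
independent sigmoids with binary cross-entropy for the 15-output
multilabel design. Optimization is Adam at its canonical rates on
mini-batches (default 64), with optional patience-based early stopping on
a held-out slice of the training set. All arithmetic is float32 and every
source of randomness is seeded, so training is reproducible.

The activation applied to the cell state on output ("hidden activation")
is configurable among sigmoid / tanh / selu / relu, defaulting to sigmoid;
gate nonlinearities are the standard sigmoid/tanh.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .categorize import ValidationError

logger = logging.getLogger(__name__)

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _act(name, x):
    if name == "sigmoid":
        return _sigmoid(x)
    if name == "tanh":
        return np.tanh(x)
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "selu":
        return np.float32(_SELU_SCALE) * np.where(
            x > 0, x, np.float32(_SELU_ALPHA) * np.expm1(x))
    raise ValidationError(f"unknown activation {name!r}")


def _act_grad(name, x, a):
    """Derivative of the activation at pre-image x (a = act(x))."""
    if name == "sigmoid":
        return a * (1.0 - a)
    if name == "tanh":
        return 1.0 - a * a
    if name == "relu":
        return (x > 0).astype(a.dtype)
    if name == "selu":
        return np.where(x > 0, np.float32(_SELU_SCALE),
                        a + np.float32(_SELU_SCALE * _SELU_ALPHA))
    raise ValidationError(f"unknown activation {name!r}")


@dataclass
class LSTMConfig:
    hidden_units: int = 100
    hidden_activation: str = "sigmoid"
    batch_size: int = 64
    epochs: int = 30
    learning_rate: float = 1e-3        # Adam defaults throughout
    output_mode: str = "multiclass3"   # or "multilabel15"
    n_outputs: int | None = None       # inferred when None
    early_stopping: bool = False
    patience: int = 3
    validation_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.hidden_units < 1 or self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("hidden_units, batch_size and epochs must be >= 1")
        if self.output_mode not in ("multiclass3", "multilabel15"):
            raise ValidationError(f"unknown output_mode {self.output_mode!r}")
        _act(self.hidden_activation, np.zeros(1, dtype=np.float32))


class LSTMClassifier:
    """Masked LSTM with a dense head over [final state, demographics]."""

    def __init__(self, input_dim: int, demo_dim: int, config: LSTMConfig):
        config.validate()
        self.config = config
        self.input_dim = input_dim
        self.demo_dim = demo_dim
        H = config.hidden_units
        K = config.n_outputs or (3 if config.output_mode == "multiclass3" else 15)
        self.n_outputs = K
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))

        def glorot(fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=(fan_in, fan_out)).astype(np.float32)

        self.Wx = glorot(input_dim, 4 * H)
        self.Wh = glorot(H, 4 * H)
        self.b = np.zeros(4 * H, dtype=np.float32)
        self.b[H:2 * H] = 1.0  # forget-gate bias
        self.Wy = glorot(H + demo_dim, K)
        self.by = np.zeros(K, dtype=np.float32)
        self._params = ["Wx", "Wh", "b", "Wy", "by"]
        self._adam_m = {p: np.zeros_like(getattr(self, p)) for p in self._params}
        self._adam_v = {p: np.zeros_like(getattr(self, p)) for p in self._params}
        self._adam_t = 0
        self._rng = rng
        self.history: list[dict] = []

    # -- forward / backward -------------------------------------------------

    def _forward(self, X, M, demo, cache: bool = False):
        B, T, _ = X.shape
        H = self.config.hidden_units
        act = self.config.hidden_activation
        h = np.zeros((B, H), dtype=np.float32)
        c = np.zeros((B, H), dtype=np.float32)
        caches = []
        for t in range(T):
            m = M[:, t].astype(np.float32)[:, None]
            z = X[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            a = _act(act, c_new)
            h_new = o * a
            if cache:
                caches.append((h, c, i, f, g, o, c_new, a, m))
            c = m * c_new + (1.0 - m) * c
            h = m * h_new + (1.0 - m) * h
        u = np.concatenate([h, demo], axis=1)
        logits = u @ self.Wy + self.by
        return (logits, u, caches) if cache else logits

    def _output_and_loss(self, logits, Y):
        eps = 1e-7
        if self.config.output_mode == "multiclass3":
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            p = e / e.sum(axis=1, keepdims=True)
            loss = -np.mean(np.log(p[np.arange(len(Y)), Y] + eps))
            dlogits = p.copy()
            dlogits[np.arange(len(Y)), Y] -= 1.0
            dlogits /= len(Y)
        else:
            p = _sigmoid(logits)
            loss = -np.mean(np.sum(Y * np.log(p + eps)
                                   + (1 - Y) * np.log(1 - p + eps), axis=1))
            dlogits = (p - Y) / len(Y)
        return p, np.float32(loss), dlogits.astype(np.float32)

    def _backward(self, X, M, dlogits, u, caches):
        H = self.config.hidden_units
        act = self.config.hidden_activation
        grads = {p: np.zeros_like(getattr(self, p)) for p in self._params}
        grads["Wy"] = u.T @ dlogits
        grads["by"] = dlogits.sum(axis=0)
        du = dlogits @ self.Wy.T
        dh = du[:, :H].copy()
        dc = np.zeros_like(dh)
        for t in range(X.shape[1] - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c_new, a, m = caches[t]
            dh_new = dh * m
            dh_skip = dh * (1.0 - m)
            dc_new = dc * m
            dc_skip = dc * (1.0 - m)
            do = dh_new * a
            dc_new = dc_new + dh_new * o * _act_grad(act, c_new, a)
            df = dc_new * c_prev
            di = dc_new * g
            dg = dc_new * i
            dzi = di * i * (1.0 - i)
            dzf = df * f * (1.0 - f)
            dzg = dg * (1.0 - g * g)
            dzo = do * o * (1.0 - o)
            dz = np.concatenate([dzi, dzf, dzg, dzo], axis=1)
            grads["Wx"] += X[:, t].T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dh = dz @ self.Wh.T + dh_skip
            dc = dc_new * f + dc_skip
        return grads

    def _adam_step(self, grads):
        self._adam_t += 1
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        t = self._adam_t
        for p in self._params:
            g = grads[p]
            self._adam_m[p] = b1 * self._adam_m[p] + (1 - b1) * g
            self._adam_v[p] = b2 * self._adam_v[p] + (1 - b2) * g * g
            mhat = self._adam_m[p] / (1 - b1 ** t)
            vhat = self._adam_v[p] / (1 - b2 ** t)
            setattr(self, p, (getattr(self, p)
                              - lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32))

    # -- public API ---------------------------------------------------------

    def fit(self, X, M, demo, Y):
        """Train on float32 arrays: X (n, T, D), M (n, T) bool, demo (n, P),
        Y int labels (multiclass) or 0/1 matrix (multilabel)."""
        cfg = self.config
        X = np.ascontiguousarray(X, dtype=np.float32)
        demo = np.ascontiguousarray(demo, dtype=np.float32)
        if cfg.output_mode == "multiclass3":
            Y = np.asarray(Y)
            if Y.ndim != 1 or ((Y < 0) | (Y >= self.n_outputs)).any():
                raise ValidationError(
                    f"multiclass labels must lie in [0, {self.n_outputs}), "
                    f"got range [{Y.min()}, {Y.max()}]")
        else:
            Y = np.asarray(Y, dtype=np.float32)
            if Y.ndim != 2 or Y.shape[1] != self.n_outputs:
                raise ValidationError(
                    f"multilabel targets must be (n, {self.n_outputs})")

        n = len(X)
        idx = np.arange(n)
        val_idx = np.array([], dtype=int)
        if cfg.early_stopping and n >= 20:
            n_val = max(1, int(round(cfg.validation_fraction * n)))
            perm = self._rng.permutation(n)
            val_idx, idx = perm[:n_val], perm[n_val:]
        best_val, best_params, wait = np.inf, None, 0
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(idx)
            losses = []
            for s in range(0, len(order), cfg.batch_size):
                batch = order[s:s + cfg.batch_size]
                logits, u, caches = self._forward(X[batch], M[batch],
                                                  demo[batch], cache=True)
                _, loss, dlogits = self._output_and_loss(logits, Y[batch])
                grads = self._backward(X[batch], M[batch], dlogits, u, caches)
                self._adam_step(grads)
                losses.append(float(loss))
            record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if len(val_idx):
                vlogits = self._forward(X[val_idx], M[val_idx], demo[val_idx])
                _, vloss, _ = self._output_and_loss(vlogits, Y[val_idx])
                record["val_loss"] = float(vloss)
                if vloss < best_val - 1e-5:
                    best_val, wait = float(vloss), 0
                    best_params = {p: getattr(self, p).copy() for p in self._params}
                else:
                    wait += 1
            self.history.append(record)
            logger.debug("epoch %d: %s", epoch, record)
            if len(val_idx) and wait >= cfg.patience:
                break
        if best_params is not None:
            for p, v in best_params.items():
                setattr(self, p, v)
        return self

    def predict_proba(self, X, M, demo, batch_size: int = 512):
        if X.shape[2] != self.input_dim or demo.shape[1] != self.demo_dim:
            raise ValidationError(
                f"expected feature dims ({self.input_dim}, demo {self.demo_dim}), "
                f"received ({X.shape[2]}, demo {demo.shape[1]})")
        out = []
        for s in range(0, len(X), batch_size):
            logits = self._forward(np.asarray(X[s:s + batch_size], dtype=np.float32),
                                   M[s:s + batch_size],
                                   np.asarray(demo[s:s + batch_size], dtype=np.float32))
            if self.config.output_mode == "multiclass3":
                z = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(z)
                out.append(e / e.sum(axis=1, keepdims=True))
            else:
                out.append(_sigmoid(logits))
        return np.concatenate(out, axis=0)
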