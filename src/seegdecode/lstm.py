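"""Sequence-to-sequence LSTM classifier in NumPy.

A single-layer LSTM with a softmax readout at every timestep, trained by
backpropagation through time with the Adam optimizer, global-norm gradient
clipping, and early stopping on a held-out validation split of the training
sequences. Designed for the small sequence counts typical of task-locked
neural recordings, where a full deep-learning framework is unnecessary;
gradients are verified against numerical differentiation in the test suite.

Sequences may have different lengths. The loss is the mean cross-entropy
over all timesteps of all sequences. Training is deterministic given the
seed (single-threaded NumPy ops only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class LSTMParams:
    """Weights: input/recurrent kernels (gate order i, f, g, o) and readout."""

    Wx: np.ndarray  # (n_features, 4*hidden)
    Wh: np.ndarray  # (hidden, 4*hidden)
    b: np.ndarray  # (4*hidden,)
    Wy: np.ndarray  # (hidden, n_classes)
    by: np.ndarray  # (n_classes,)

    def as_list(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b, self.Wy, self.by]

    def copy(self) -> "LSTMParams":
        return LSTMParams(*(p.copy() for p in self.as_list()))


def _init_params(
    n_features: int,
    hidden: int,
    n_classes: int,
    rng: np.random.Generator,
    zero_readout: bool = False,
) -> LSTMParams:
    def glorot(n_in: int, n_out: int) -> np.ndarray:
        s = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-s, s, size=(n_in, n_out))

    b = np.zeros(4 * hidden)
    b[hidden : 2 * hidden] = 1.0  # forget-gate bias: remember by default
    wy = np.zeros((hidden, n_classes)) if zero_readout else glorot(hidden, n_classes)
    return LSTMParams(
        Wx=glorot(n_features, 4 * hidden),
        Wh=glorot(hidden, 4 * hidden),
        b=b,
        Wy=wy,
        by=np.zeros(n_classes),
    )


def _forward(x: np.ndarray, p: LSTMParams) -> tuple[np.ndarray, dict]:
    """Run one sequence (T, F); returns per-step class probabilities and cache."""
    T = x.shape[0]
    H = p.Wh.shape[0]
    h = np.zeros(H)
    c = np.zeros(H)
    cache = {"x": x, "i": [], "f": [], "g": [], "o": [], "c": [], "h": [], "c_prev": [], "h_prev": []}
    hs = np.empty((T, H))
    for t in range(T):
        z = x[t] @ p.Wx + h @ p.Wh + p.b
        i = _sigmoid(z[:H])
        f = _sigmoid(z[H : 2 * H])
        g = np.tanh(z[2 * H : 3 * H])
        o = _sigmoid(z[3 * H :])
        cache["c_prev"].append(c)
        cache["h_prev"].append(h)
        c = f * c + i * g
        h = o * np.tanh(c)
        for k, v in (("i", i), ("f", f), ("g", g), ("o", o), ("c", c), ("h", h)):
            cache[k].append(v)
        hs[t] = h
    probs = _softmax(hs @ p.Wy + p.by)
    cache["hs"] = hs
    cache["probs"] = probs
    return probs, cache


def _backward(labels: np.ndarray, p: LSTMParams, cache: dict, scale: float) -> LSTMParams:
    """Gradient of ``scale * sum_t CE(probs_t, labels_t)`` w.r.t. parameters."""
    x, hs, probs = cache["x"], cache["hs"], cache["probs"]
    T, H = hs.shape
    dlogits = probs.copy()
    dlogits[np.arange(T), labels] -= 1.0
    dlogits *= scale
    g = LSTMParams(
        Wx=np.zeros_like(p.Wx),
        Wh=np.zeros_like(p.Wh),
        b=np.zeros_like(p.b),
        Wy=hs.T @ dlogits,
        by=dlogits.sum(axis=0),
    )
    dh_next = np.zeros(H)
    dc_next = np.zeros(H)
    for t in range(T - 1, -1, -1):
        i, f, gt, o = cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t]
        c, c_prev, h_prev = cache["c"][t], cache["c_prev"][t], cache["h_prev"][t]
        dh = dlogits[t] @ p.Wy.T + dh_next
        tanh_c = np.tanh(c)
        do = dh * tanh_c
        dc = dh * o * (1.0 - tanh_c**2) + dc_next
        di = dc * gt
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - gt**2),
                do * o * (1.0 - o),
            ]
        )
        g.Wx += np.outer(x[t], dz)
        g.Wh += np.outer(h_prev, dz)
        g.b += dz
        dh_next = dz @ p.Wh.T
        dc_next = dc * f
    return g


def sequence_loss(
    sequences: list[np.ndarray], labels: list[np.ndarray], p: LSTMParams
) -> float:
    """Mean cross-entropy over all timesteps of all sequences."""
    total, count = 0.0, 0
    for x, y in zip(sequences, labels):
        probs, _ = _forward(x, p)
        total += -np.sum(np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)))
        count += len(y)
    return total / count


def loss_and_gradients(
    sequences: list[np.ndarray], labels: list[np.ndarray], p: LSTMParams
) -> tuple[float, LSTMParams]:
    n_steps = sum(len(y) for y in labels)
    total = 0.0
    grads = LSTMParams(*(np.zeros_like(w) for w in p.as_list()))
    for x, y in zip(sequences, labels):
        probs, cache = _forward(x, p)
        total += -np.sum(np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)))
        gi = _backward(np.asarray(y), p, cache, scale=1.0 / n_steps)
        for acc, gw in zip(grads.as_list(), gi.as_list()):
            acc += gw
    return total / n_steps, grads


@dataclass
class LSTMClassifier:
    """Window-wise sequence classifier: one softmax decision per timestep.

    Parameters
    ----------
    hidden_units : int
        Size of the LSTM state.
    learning_rate, max_epochs, patience : Adam step size, epoch cap, and
        early-stopping patience (epochs without validation improvement).
    validation_fraction : fraction of training sequences held out for early
        stopping (at least one sequence; disabled when only one sequence).
    clip_norm : global gradient-norm ceiling.
    seed : controls initialization and the validation split.
    """

    hidden_units: int = 64
    learning_rate: float = 0.01
    max_epochs: int = 200
    patience: int = 20
    validation_fraction: float = 0.2
    clip_norm: float = 5.0
    seed: int = 0
    n_classes_: int | None = None
    params_: LSTMParams | None = field(default=None, repr=False)

    def fit(
        self, sequences: list[np.ndarray], labels: list[np.ndarray]
    ) -> "LSTMClassifier":
        if not sequences:
            raise ValueError("no training sequences")
        n_features = sequences[0].shape[1]
        self.n_classes_ = int(max(int(np.max(y)) for y in labels)) + 1
        rng = np.random.default_rng(self.seed)
        # zero readout weights + prior-initialized readout bias: the model
        # starts as exactly the class-prior predictor, so uninformative data
        # degrades to the majority class instead of an arbitrary argmax
        p = _init_params(
            n_features, self.hidden_units, self.n_classes_, rng, zero_readout=True
        )
        counts = np.bincount(
            np.concatenate([np.asarray(y) for y in labels]),
            minlength=self.n_classes_,
        )
        p.by = np.log(np.maximum(counts, 1) / max(counts.sum(), 1))

        n_val = int(round(self.validation_fraction * len(sequences)))
        n_val = min(max(n_val, 1), len(sequences) - 1) if len(sequences) > 1 else 0
        order = rng.permutation(len(sequences))
        val_idx = set(order[:n_val].tolist())
        train_s = [sequences[i] for i in range(len(sequences)) if i not in val_idx]
        train_y = [labels[i] for i in range(len(sequences)) if i not in val_idx]
        val_s = [sequences[i] for i in sorted(val_idx)]
        val_y = [labels[i] for i in sorted(val_idx)]

        m = [np.zeros_like(w) for w in p.as_list()]
        v = [np.zeros_like(w) for w in p.as_list()]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        # the untrained (prior-predicting) model competes in model selection:
        # an epoch is kept only if it beats it on the held-out sequences
        best_loss = sequence_loss(val_s, val_y, p) if val_s else sequence_loss(
            train_s, train_y, p
        )
        best_params, since_best = p.copy(), 0
        for epoch in range(1, self.max_epochs + 1):
            loss, grads = loss_and_gradients(train_s, train_y, p)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss}"
                )
            gl = grads.as_list()
            norm = np.sqrt(sum(float(np.sum(g**2)) for g in gl))
            if norm > self.clip_norm:
                gl = [g * (self.clip_norm / norm) for g in gl]
            pl = p.as_list()
            for j in range(len(pl)):
                m[j] = beta1 * m[j] + (1 - beta1) * gl[j]
                v[j] = beta2 * v[j] + (1 - beta2) * gl[j] ** 2
                mhat = m[j] / (1 - beta1**epoch)
                vhat = v[j] / (1 - beta2**epoch)
                pl[j] -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            monitor = sequence_loss(val_s, val_y, p) if val_s else loss
            if monitor < best_loss - 1e-6:
                best_loss, best_params, since_best = monitor, p.copy(), 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    logger.debug("early stop at epoch %d (best %g)", epoch, best_loss)
                    break
        self.params_ = best_params
        return self

    def predict_proba(self, sequences: list[np.ndarray]) -> list[np.ndarray]:
        if self.params_ is None:
            raise RuntimeError("classifier is not fitted")
        return [_forward(x, self.params_)[0] for x in sequences]

    def predict(self, sequences: list[np.ndarray]) -> list[np.ndarray]:
        return [np.argmax(pr, axis=1) for pr in self.predict_proba(sequences)]
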