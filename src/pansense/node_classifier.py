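"""Per-node activity classifiers M_i.

Two interchangeable backends sit behind one train/predict/evaluate contract:

``light``
    Per-channel summary features (mean, standard deviation, energy, dominant
    frequency) feeding a multinomial logistic layer. Deterministic for a
    fixed seed and fast enough that the whole pipeline's tests run in
    seconds. This is the default for desk-scale experiments.

``rnn``
    A many-to-one recurrent network: LSTM(60) -> dropout(0.5) -> dense(60,
    relu) -> softmax, trained with categorical cross-entropy and Adam in
    mini-batches of 64 for at most 40 epochs. Implemented here as a compact
    numpy network (forward + backprop-through-time), gradient-checked in the
    test suite. Dropout acts only at training time; at inference the softmax
    output is the node's voting-weight vector.

Either way, a prediction is a full probability vector over the 8 classes;
the winning class and its probability are what a node would transmit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .domain import (
    ActivityLabel,
    ClassificationResult,
    N_CLASSES,
    NodePosition,
    activity_by_index,
    canonical_activity_order,
)
from .preprocess import SensorWindow, WindowedDataset

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "train",
    "predict",
    "predict_dataset",
    "evaluate",
    "extract_features",
]

RNN_DEFAULTS = {
    "lstm_units": 60,
    "dropout_rate": 0.5,
    "dense_units": 60,
    "dense_activation": "relu",
    "output_activation": "softmax",
    "loss": "categorical_crossentropy",
    "optimizer": "adam",
    "batch_size": 64,
    "max_epochs": 40,
}

LIGHT_DEFAULTS = {
    "features": "per-channel mean, sd, energy, dominant frequency",
    "C": 10.0,  # inverse L2 regularisation strength of the logistic layer
}


@dataclass
class ModelSpec:
    backend: str = "light"
    rnn: dict = field(default_factory=lambda: dict(RNN_DEFAULTS))
    light: dict = field(default_factory=lambda: dict(LIGHT_DEFAULTS))
    window_size: int | None = None  # None: taken from the training data

    def __post_init__(self) -> None:
        if self.backend not in ("light", "rnn"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.rnn.get("max_epochs", 0) > 50:
            raise ValueError("max_epochs must be <= 50")


@dataclass
class TrainedModel:
    spec: ModelSpec
    position: NodePosition
    class_order: list[ActivityLabel]
    window_size: int
    sample_rate: float
    training_log: list[dict]
    _backend: object = None

    def predict_proba(self, values: np.ndarray) -> np.ndarray:
        """Probability matrix (n, 8) for a stack of windows (n, WS, 6)."""
        return self._backend.predict_proba(values, self.sample_rate)


# ----------------------------------------------------------------- light ---

def extract_features(values: np.ndarray, rate: float,
                     peak_gate: float = 3.0) -> np.ndarray:
    """Summary features per channel: mean, sd, energy, dominant frequency.

    ``values`` is (n, WS, C); returns (n, 4*C). The dominant frequency is
    the argmax of the non-DC rfft magnitude, in Hz, reported as 0 when the
    peak is not prominent (below ``peak_gate`` times the median bin
    magnitude) — a flat spectrum has no meaningful dominant frequency and
    reporting its argmax would inject uniform noise into the feature.
    """
    values = np.asarray(values, dtype=float)
    n, ws, c = values.shape
    mean = values.mean(axis=1)
    sd = values.std(axis=1)
    energy = (values ** 2).mean(axis=1)
    mag = np.abs(np.fft.rfft(values, axis=1))[:, 1:, :]
    freqs = np.fft.rfftfreq(ws, d=1.0 / rate)
    dom = freqs[1:][mag.argmax(axis=1)]
    dom = np.where(mag.max(axis=1) > peak_gate * np.median(mag, axis=1), dom, 0.0)
    return np.concatenate([mean, sd, energy, dom], axis=1)


class _LightBackend:
    """StandardScaler + multinomial logistic regression over summary features."""

    def __init__(self, C: float, seed: int):
        self.scaler = StandardScaler()
        self.clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)

    def fit(self, values: np.ndarray, y: np.ndarray, rate: float) -> list[dict]:
        X = self.scaler.fit_transform(extract_features(values, rate))
        self.clf.fit(X, y)
        acc = float(self.clf.score(X, y))
        return [{"epoch": 0, "train_accuracy": acc, "loss": float("nan")}]

    def predict_proba(self, values: np.ndarray, rate: float) -> np.ndarray:
        X = self.scaler.transform(extract_features(values, rate))
        proba = self.clf.predict_proba(X)
        out = np.zeros((proba.shape[0], N_CLASSES))
        out[:, self.clf.classes_.astype(int)] = proba
        return out


# ------------------------------------------------------------------- rnn ---

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _LSTMBackend:
    """Minimal numpy LSTM classifier with the fixed recurrent architecture.

    Gate layout in the stacked weight matrices is (input, forget, cell,
    output). The last hidden state feeds a relu dense layer and a softmax
    output; training is full BPTT with Adam.
    """

    def __init__(self, n_features: int, hidden: int, dense: int, n_out: int,
                 dropout: float, seed: int):
        rng = np.random.default_rng(seed)
        self.hidden, self.dropout = hidden, dropout

        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-lim, lim, size=shape)

        self.params = {
            "Wx": glorot((n_features, 4 * hidden)),
            "Wh": glorot((hidden, 4 * hidden)),
            "b": np.zeros(4 * hidden),
            "W1": glorot((hidden, dense)),
            "b1": np.zeros(dense),
            "W2": glorot((dense, n_out)),
            "b2": np.zeros(n_out),
        }
        # forget-gate bias at 1: standard stable initialisation
        self.params["b"][hidden:2 * hidden] = 1.0
        self._adam = {k: [np.zeros_like(v), np.zeros_like(v)]
                      for k, v in self.params.items()}
        self._adam_t = 0
        self._rng = rng

    # -- forward -----------------------------------------------------------

    def _lstm_forward(self, X: np.ndarray):
        B, T, _ = X.shape
        H = self.hidden
        p = self.params
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            z = X[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = 1.0 / (1.0 + np.exp(-z[:, :H]))
            f = 1.0 / (1.0 + np.exp(-z[:, H:2 * H]))
            g = np.tanh(z[:, 2 * H:3 * H])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * H:]))
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            cache.append((X[:, t], h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
        return h, cache

    def _head_forward(self, h: np.ndarray, train: bool):
        p = self.params
        if train and self.dropout > 0:
            mask = (self._rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
        else:
            mask = np.ones_like(h)
        hd = h * mask
        a1 = hd @ p["W1"] + p["b1"]
        r1 = np.maximum(a1, 0.0)
        logits = r1 @ p["W2"] + p["b2"]
        return _softmax(logits), (hd, mask, a1, r1)

    def predict_proba(self, X: np.ndarray, rate: float | None = None) -> np.ndarray:
        h, _ = self._lstm_forward(np.asarray(X, dtype=float))
        proba, _ = self._head_forward(h, train=False)
        return proba

    # -- backward ----------------------------------------------------------

    def _grads(self, X: np.ndarray, y_onehot: np.ndarray):
        B = X.shape[0]
        H = self.hidden
        p = self.params
        h_last, cache = self._lstm_forward(X)
        proba, (hd, mask, a1, r1) = self._head_forward(h_last, train=True)
        loss = -np.log(np.clip((proba * y_onehot).sum(axis=1), 1e-12, None)).mean()

        g = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = (proba - y_onehot) / B
        g["W2"] = r1.T @ dlogits
        g["b2"] = dlogits.sum(axis=0)
        dr1 = dlogits @ p["W2"].T
        da1 = dr1 * (a1 > 0)
        g["W1"] = hd.T @ da1
        g["b1"] = da1.sum(axis=0)
        dh = (da1 @ p["W1"].T) * mask
        dc = np.zeros_like(dh)
        for t in range(len(cache) - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, gg, o, c_new = cache[t]
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c ** 2)
            di = dc * gg
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - gg ** 2), do * o * (1 - o)], axis=1)
            g["Wx"] += x_t.T @ dz
            g["Wh"] += h_prev.T @ dz
            g["b"] += dz.sum(axis=0)
            dh = dz @ p["Wh"].T
            dc = dc * f
        return loss, proba, g

    def _adam_step(self, grads: dict, lr: float = 1e-3,
                   b1: float = 0.9, b2: float = 0.999, eps: float = 1e-7):
        self._adam_t += 1
        t = self._adam_t
        for k, gr in grads.items():
            m, v = self._adam[k]
            m[:] = b1 * m + (1 - b1) * gr
            v[:] = b2 * v + (1 - b2) * gr ** 2
            mhat = m / (1 - b1 ** t)
            vhat = v / (1 - b2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit(self, values: np.ndarray, y: np.ndarray, rate: float,
            batch_size: int, max_epochs: int) -> list[dict]:
        X = np.asarray(values, dtype=float)
        onehot = np.eye(N_CLASSES)[y]
        n = X.shape[0]
        log = []
        for epoch in range(max_epochs):
            order = self._rng.permutation(n)
            losses = []
            for s in range(0, n, batch_size):
                idx = order[s:s + batch_size]
                loss, _, grads = self._grads(X[idx], onehot[idx])
                self._adam_step(grads)
                losses.append(loss)
            acc = float((self.predict_proba(X).argmax(axis=1) == y).mean())
            log.append({"epoch": epoch, "train_accuracy": acc,
                        "loss": float(np.mean(losses))})
        return log


# ------------------------------------------------------------- interface ---

def train(spec: ModelSpec, train_set: WindowedDataset, seed: int = 0) -> TrainedModel:
    """Fit one node's classifier on a single-position windowed dataset."""
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    positions = {w.position.code for w in train_set.windows}
    if len(positions) != 1:
        raise ValueError(f"training set mixes positions {sorted(positions)}")
    ws = train_set.windows[0].window_size
    if spec.window_size is not None and spec.window_size != ws:
        raise ValueError(
            f"spec expects window_size {spec.window_size}, data has {ws}")
    y = train_set.labels()
    present = set(y.tolist())
    if len(present) < N_CLASSES:
        missing = [a.name for a in canonical_activity_order() if a.index not in present]
        warnings.warn(f"training set is missing classes: {missing}")

    values = np.stack([w.values for w in train_set.windows])
    rate = train_set.config.sample_rate
    if spec.backend == "light":
        backend = _LightBackend(C=spec.light.get("C", 10.0), seed=seed)
        log = backend.fit(values, y, rate)
    else:
        backend = _LSTMBackend(
            n_features=values.shape[2],
            hidden=spec.rnn["lstm_units"],
            dense=spec.rnn["dense_units"],
            n_out=N_CLASSES,
            dropout=spec.rnn["dropout_rate"],
            seed=seed,
        )
        log = backend.fit(values, y, rate,
                          batch_size=spec.rnn["batch_size"],
                          max_epochs=spec.rnn["max_epochs"])
    return TrainedModel(
        spec=spec,
        position=train_set.windows[0].position,
        class_order=canonical_activity_order(),
        window_size=ws,
        sample_rate=rate,
        training_log=log,
        _backend=backend,
    )


def predict(model: TrainedModel, window: SensorWindow, step: int | None = None) -> ClassificationResult:
    """Classify one window; a pure function of (model, window)."""
    if window.position != model.position:
        raise ValueError(
            f"window from {window.position.code} fed to a {model.position.code} model")
    if window.window_size != model.window_size:
        raise ValueError(
            f"window size {window.window_size} != model's {model.window_size}")
    if not np.all(np.isfinite(window.values)):
        raise ValueError("window contains non-finite values")
    weights = model.predict_proba(window.values[None])[0]
    label = activity_by_index(int(weights.argmax()))
    return ClassificationResult(
        node=model.position,
        step=window.step if step is None else step,
        label=label,
        weight=float(weights[label.index]),
        weights=weights,
    )


def predict_dataset(model: TrainedModel, dataset: WindowedDataset) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised prediction: (labels (n,), weight matrix (n, 8))."""
    values = np.stack([w.values for w in dataset.windows])
    proba = model.predict_proba(values)
    return proba.argmax(axis=1), proba


def evaluate(model: TrainedModel, test_set: WindowedDataset) -> tuple[float, np.ndarray]:
    """Accuracy and the 8x8 confusion matrix (rows true, columns predicted)."""
    if len(test_set) == 0:
        raise ValueError("test set is empty")
    pred, _ = predict_dataset(model, test_set)
    true = test_set.labels()
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(cm, (true, pred), 1)
    return float(np.trace(cm) / cm.sum()), cm


# ------------------------------------------------------------ persistence --

def save_model(model: TrainedModel, directory: str | Path) -> Path:
    """Write spec.json, class_order.json, training_log.csv and weights."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "spec.json").write_text(json.dumps({
        "backend": model.spec.backend, "rnn": model.spec.rnn,
        "light": {k: v for k, v in model.spec.light.items()},
        "position": model.position.code, "window_size": model.window_size,
        "sample_rate": model.sample_rate,
    }, indent=1))
    (directory / "class_order.json").write_text(
        json.dumps([a.name for a in model.class_order]))
    import pandas as pd

    pd.DataFrame(model.training_log).to_csv(directory / "training_log.csv", index=False)
    b = model._backend
    if model.spec.backend == "light":
        np.savez(directory / "weights.npz",
                 scaler_mean=b.scaler.mean_, scaler_scale=b.scaler.scale_,
                 coef=b.clf.coef_, intercept=b.clf.intercept_,
                 classes=b.clf.classes_)
    else:
        np.savez(directory / "weights.npz", **b.params)
    return directory
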