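"""Fixed, pretrained recurrent sequence classifier.

Two stacked LSTM layers, each followed by dropout (rate 0.5, training only),
then a dense softmax head, trained once on the reference dataset with
categorical cross-entropy and Adam with multiplicative learning-rate decay.
Each series is fed as a length-L sequence of 1-dimensional observations.

Implemented directly on NumPy (forward + backpropagation through time) so the
package has no deep-learning framework dependency; the gradients are verified
against numerical differentiation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import LabeledSeriesSet
from .errors import ConfigurationError, FormatError

__all__ = [
    "ClassifierConfig",
    "TrainedClassifier",
    "train_classifier",
    "predict",
    "cross_entropy",
    "one_hot",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture and optimization settings.

    ``learning_rate`` is the Adam base step and ``lr_decay`` a multiplicative
    per-step decay: lr_t = learning_rate / (1 + lr_decay * t).
    """

    units: int = 64
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    lr_decay: float = 1e-4
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.units < 1:
            raise ConfigurationError(f"units must be >= 1, got {self.units}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError(
                f"dropout_rate must be in [0, 1), got {self.dropout_rate}"
            )
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Symbolic-function encoding y_ic in class-index order."""
    out = np.zeros((labels.shape[0], n_classes))
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out


def cross_entropy(onehot: np.ndarray, probs: np.ndarray) -> float:
    """L = -(1/N) sum_i sum_c y_ic log(p_ic), probs clipped to [1e-12, 1]."""
    onehot = np.asarray(onehot, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if onehot.shape != probs.shape:
        raise FormatError(f"shape mismatch: {onehot.shape} vs {probs.shape}")
    clipped = np.clip(probs, 1e-12, 1.0)
    return float(-(onehot * np.log(clipped)).sum() / onehot.shape[0])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _init_lstm_params(rng: np.random.Generator, in_dim: int, units: int) -> dict:
    k = 1.0 / np.sqrt(units)
    p = {
        "Wx": rng.uniform(-k, k, size=(in_dim, 4 * units)),
        "Wh": rng.uniform(-k, k, size=(units, 4 * units)),
        "b": np.zeros(4 * units),
    }
    p["b"][units : 2 * units] = 1.0  # forget-gate bias
    return p


def _lstm_forward(p: dict, x: np.ndarray) -> tuple[np.ndarray, dict]:
    """x: (B, T, D) -> h_seq: (B, T, H) plus a cache for backprop."""
    B, T, _ = x.shape
    H = p["Wh"].shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    h_seq = np.empty((B, T, H))
    cache = {"x": x, "i": [], "f": [], "g": [], "o": [], "c": [], "tc": [],
             "h_prev": [], "c_prev": []}
    for t in range(T):
        z = x[:, t, :] @ p["Wx"] + h @ p["Wh"] + p["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        cache["h_prev"].append(h)
        cache["c_prev"].append(c)
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        h_seq[:, t, :] = h
        for key, val in (("i", i), ("f", f), ("g", g), ("o", o), ("c", c), ("tc", tc)):
            cache[key].append(val)
    return h_seq, cache


def _lstm_backward(p: dict, cache: dict, dh_seq: np.ndarray) -> tuple[dict, np.ndarray]:
    """dh_seq: (B, T, H) upstream grads per timestep -> (param grads, dx_seq)."""
    x = cache["x"]
    B, T, _ = x.shape
    H = p["Wh"].shape[0]
    grads = {"Wx": np.zeros_like(p["Wx"]), "Wh": np.zeros_like(p["Wh"]),
             "b": np.zeros_like(p["b"])}
    dx = np.zeros_like(x)
    dh = np.zeros((B, H))
    dc = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        dh = dh + dh_seq[:, t, :]
        i, f, g, o = cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t]
        tc = cache["tc"][t]
        dc = dc + dh * o * (1.0 - tc * tc)
        do = dh * tc
        df = dc * cache["c_prev"][t]
        di = dc * g
        dg = dc * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        grads["Wx"] += x[:, t, :].T @ dz
        grads["Wh"] += cache["h_prev"][t].T @ dz
        grads["b"] += dz.sum(axis=0)
        dx[:, t, :] = dz @ p["Wx"].T
        dh = dz @ p["Wh"].T
        dc = dc * f
    return grads, dx


def _forward(
    params: dict,
    x_seq: np.ndarray,
    masks: tuple[np.ndarray, np.ndarray] | None,
) -> tuple[np.ndarray, dict]:
    """Full model forward; masks are inverted-dropout masks or None (inference)."""
    h1, cache1 = _lstm_forward(params["lstm1"], x_seq)
    h1d = h1 if masks is None else h1 * masks[0]
    h2, cache2 = _lstm_forward(params["lstm2"], h1d)
    last = h2[:, -1, :]
    lastd = last if masks is None else last * masks[1]
    logits = lastd @ params["W_out"] + params["b_out"]
    probs = _softmax(logits)
    cache = {"cache1": cache1, "cache2": cache2, "h1": h1, "h2": h2,
             "lastd": lastd, "masks": masks}
    return probs, cache


def _backward(params: dict, cache: dict, probs: np.ndarray, onehot: np.ndarray) -> dict:
    B = probs.shape[0]
    masks = cache["masks"]
    dlogits = (probs - onehot) / B
    grads = {
        "W_out": cache["lastd"].T @ dlogits,
        "b_out": dlogits.sum(axis=0),
    }
    dlast = dlogits @ params["W_out"].T
    if masks is not None:
        dlast = dlast * masks[1]
    dh2_seq = np.zeros_like(cache["h2"])
    dh2_seq[:, -1, :] = dlast
    grads2, dh1d = _lstm_backward(params["lstm2"], cache["cache2"], dh2_seq)
    if masks is not None:
        dh1d = dh1d * masks[0]
    grads1, _ = _lstm_backward(params["lstm1"], cache["cache1"], dh1d)
    grads["lstm1"] = grads1
    grads["lstm2"] = grads2
    return grads


def _iter_params(params: dict):
    yield "W_out", params, "W_out"
    yield "b_out", params, "b_out"
    for layer in ("lstm1", "lstm2"):
        for name in ("Wx", "Wh", "b"):
            yield f"{layer}.{name}", params[layer], name


class _Adam:
    def __init__(self, params: dict, lr: float, decay: float):
        self.lr = lr
        self.decay = decay
        self.t = 0
        self.m = {k: np.zeros_like(d[n]) for k, d, n in _iter_params(params)}
        self.v = {k: np.zeros_like(d[n]) for k, d, n in _iter_params(params)}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        lr_t = self.lr / (1.0 + self.decay * self.t)
        b1, b2, eps = 0.9, 0.999, 1e-8
        for key, holder, name in _iter_params(params):
            g = grads[name] if "." not in key else grads[key.split(".")[0]][name]
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1 ** self.t)
            vhat = self.v[key] / (1 - b2 ** self.t)
            holder[name] = holder[name] - lr_t * mhat / (np.sqrt(vhat) + eps)


@dataclass
class TrainedClassifier:
    """Opaque trained parameters plus class names and per-epoch history."""

    params: dict
    class_names: tuple[str, ...]
    config: ClassifierConfig
    series_length: int = 0
    history: dict = field(default_factory=lambda: {"loss": [], "accuracy": []})
    train_calls: int = 1

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


def _init_params(rng: np.random.Generator, units: int, n_classes: int) -> dict:
    k = 1.0 / np.sqrt(units)
    return {
        "lstm1": _init_lstm_params(rng, 1, units),
        "lstm2": _init_lstm_params(rng, units, units),
        "W_out": rng.uniform(-k, k, size=(units, n_classes)),
        "b_out": np.zeros(n_classes),
    }


def train_classifier(
    train_data: LabeledSeriesSet, cfg: ClassifierConfig
) -> TrainedClassifier:
    """Train the stacked recurrent model once on the (normalized) reference set.

    History records deterministic full-set loss and accuracy (inference mode,
    dropout off) after every epoch.
    """
    if np.unique(train_data.labels).size < 2:
        raise ConfigurationError("training data must contain at least 2 classes")
    rng = np.random.default_rng(cfg.seed)
    n_classes = train_data.n_classes
    params = _init_params(rng, cfg.units, n_classes)
    X = train_data.values[:, :, None]
    Y = one_hot(train_data.labels, n_classes)
    S = X.shape[0]
    opt = _Adam(params, cfg.learning_rate, cfg.lr_decay)
    keep = 1.0 - cfg.dropout_rate
    history = {"loss": [], "accuracy": []}
    for _ in range(cfg.epochs):
        order = rng.permutation(S)
        for start in range(0, S, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            if cfg.dropout_rate > 0:
                m1 = rng.binomial(1, keep, size=(len(idx), X.shape[1], cfg.units)) / keep
                m2 = rng.binomial(1, keep, size=(len(idx), cfg.units)) / keep
                masks = (m1, m2)
            else:
                masks = None
            probs, cache = _forward(params, xb, masks)
            grads = _backward(params, cache, probs, yb)
            opt.step(params, grads)
        probs, _ = _forward(params, X, None)
        history["loss"].append(cross_entropy(Y, probs))
        history["accuracy"].append(
            float((probs.argmax(axis=1) == train_data.labels).mean())
        )
    return TrainedClassifier(
        params=params,
        class_names=train_data.class_names,
        config=cfg,
        series_length=train_data.series_length,
        history=history,
    )


def predict(
    model: TrainedClassifier, data: LabeledSeriesSet
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic inference: (argmax labels, per-class probability matrix)."""
    if data.series_length != model.series_length:
        raise FormatError(
            f"data width {data.series_length} does not match training width "
            f"{model.series_length}"
        )
    probs, _ = _forward(model.params, data.values[:, :, None], None)
    return probs.argmax(axis=1), probs
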