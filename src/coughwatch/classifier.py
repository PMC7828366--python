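"""Binary cough/non-cough classifier over log-mel segments.

The network is the recurrent architecture used by the monitoring system:
the mel-frame sequence feeds two stacked LSTM layers of 256 units, the last
hidden state feeds a fully connected layer of 64 units (ReLU), then a
dropout layer with probability 0.3, and a 2-way softmax output.

Forward pass, backpropagation through time, and the Adam optimiser are
implemented directly on numpy in float32.  Training is fully deterministic
given the config seed: weight initialisation, batch shuffling and dropout
masks all draw from generators derived from it.

Candidate segments come from an onset gate that fires far more often on
non-cough transients than on coughs, so the cross-entropy loss is weighted
by inverse class frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .features import LogMelSpectrogram, MelParams

__all__ = [
    "TrainParams",
    "ClassifierConfig",
    "LabeledExample",
    "Prediction",
    "CoughClassifier",
    "build_model",
    "train",
    "predict",
    "save_model",
    "load_model",
]

LABELS = ("non_cough", "cough")  # class index order; p_cough = probs[:, 1]


@dataclass(frozen=True)
class TrainParams:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 5
    val_fraction: float = 0.15
    grad_clip: float = 5.0


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture and training hyperparameters.

    The architecture fields default to the deployed network (2 x LSTM(256),
    dense 64, dropout 0.3, softmax over 2 classes) and are exposed only so
    tests can run scaled-down variants.
    """

    lstm_layers: int = 2
    lstm_units: int = 256
    fc_units: int = 64
    dropout_p: float = 0.3
    n_classes: int = 2
    train_params: TrainParams = field(default_factory=TrainParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.n_classes != 2:
            raise ValueError("binary classifier: n_classes must be 2")
        if min(self.lstm_layers, self.lstm_units, self.fc_units) < 1:
            raise ValueError("layer sizes must be >= 1")


@dataclass(frozen=True)
class LabeledExample:
    """A training/evaluation item: features, class, and provenance for grouping."""

    spectrogram: LogMelSpectrogram
    label: Literal["cough", "non_cough"]
    recording_id: str

    def __post_init__(self) -> None:
        if not self.recording_id:
            raise ValueError("recording_id must be non-empty (grouped folds depend on it)")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class Prediction:
    segment_ref: tuple[str, float]
    p_cough: float
    label: Literal["cough", "non_cough"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out)).astype(np.float32)


class CoughClassifier:
    """Model handle: weights, feature normalisation, and the feature contract."""

    def __init__(self, config: ClassifierConfig, n_mels: int, mel_params: MelParams | None = None):
        self.config = config
        self.n_mels = n_mels
        self.mel_params = mel_params or MelParams()
        if self.mel_params.n_mels != n_mels:
            raise ValueError("n_mels disagrees with mel_params")
        rng = np.random.default_rng(config.seed)
        H = config.lstm_units
        self.lstm: list[dict[str, np.ndarray]] = []
        d_in = n_mels
        for _ in range(config.lstm_layers):
            W = _glorot(rng, d_in + H, 4 * H)
            b = np.zeros(4 * H, dtype=np.float32)
            b[H : 2 * H] = 1.0  # forget-gate bias
            self.lstm.append({"W": W, "b": b})
            d_in = H
        self.Wd = _glorot(rng, H, config.fc_units)
        self.bd = np.zeros(config.fc_units, dtype=np.float32)
        self.Wo = _glorot(rng, config.fc_units, config.n_classes)
        self.bo = np.zeros(config.n_classes, dtype=np.float32)
        # feature standardisation, fit at training time
        self.feat_mean = np.zeros(n_mels, dtype=np.float32)
        self.feat_std = np.ones(n_mels, dtype=np.float32)
        self.trained = False

    # -- introspection -------------------------------------------------------

    @property
    def layer_inventory(self) -> list[tuple]:
        """Ordered layer listing, e.g. [('lstm', 256), ('lstm', 256),
        ('dense', 64), ('dropout', 0.3), ('softmax', 2)]."""
        inv: list[tuple] = [("lstm", self.config.lstm_units) for _ in self.lstm]
        inv.append(("dense", self.config.fc_units))
        inv.append(("dropout", self.config.dropout_p))
        inv.append(("softmax", self.config.n_classes))
        return inv

    def parameters(self) -> list[np.ndarray]:
        ps = []
        for layer in self.lstm:
            ps += [layer["W"], layer["b"]]
        ps += [self.Wd, self.bd, self.Wo, self.bo]
        return ps

    # -- forward / backward --------------------------------------------------

    def _lstm_forward(self, X: np.ndarray, layer: dict) -> tuple[np.ndarray, dict]:
        B, T, D = X.shape
        H = self.config.lstm_units
        W, b = layer["W"], layer["b"]
        Zx = (X.reshape(B * T, D) @ W[:D]).reshape(B, T, 4 * H)
        h = np.zeros((B, H), dtype=np.float32)
        c = np.zeros((B, H), dtype=np.float32)
        Hs = np.zeros((B, T, H), dtype=np.float32)
        cache = {
            "X": X,
            "gates": np.zeros((B, T, 4 * H), dtype=np.float32),
            "C": np.zeros((B, T, H), dtype=np.float32),
            "Cprev": np.zeros((B, T, H), dtype=np.float32),
        }
        Wh = W[D:]
        for t in range(T):
            z = Zx[:, t] + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            cache["Cprev"][:, t] = c
            c = f * c + i * g
            h = o * np.tanh(c)
            cache["gates"][:, t, :H] = i
            cache["gates"][:, t, H : 2 * H] = f
            cache["gates"][:, t, 2 * H : 3 * H] = g
            cache["gates"][:, t, 3 * H :] = o
            cache["C"][:, t] = c
            Hs[:, t] = h
        cache["Hs"] = Hs
        return Hs, cache

    def _lstm_backward(self, dHs: np.ndarray, layer: dict, cache: dict):
        X, Hs = cache["X"], cache["Hs"]
        B, T, D = X.shape
        H = self.config.lstm_units
        W = layer["W"]
        Wh = W[D:]
        dZ = np.zeros((B, T, 4 * H), dtype=np.float32)
        dh_next = np.zeros((B, H), dtype=np.float32)
        dc_next = np.zeros((B, H), dtype=np.float32)
        for t in range(T - 1, -1, -1):
            gates = cache["gates"][:, t]
            i, f = gates[:, :H], gates[:, H : 2 * H]
            g, o = gates[:, 2 * H : 3 * H], gates[:, 3 * H :]
            tc = np.tanh(cache["C"][:, t])
            dh = dHs[:, t] + dh_next
            dc = dh * o * (1 - tc * tc) + dc_next
            dz = dZ[:, t]
            dz[:, :H] = dc * g * i * (1 - i)
            dz[:, H : 2 * H] = dc * cache["Cprev"][:, t] * f * (1 - f)
            dz[:, 2 * H : 3 * H] = dc * i * (1 - g * g)
            dz[:, 3 * H :] = dh * tc * o * (1 - o)
            dh_next = dz @ Wh.T
            dc_next = dc * f
        dW = np.zeros_like(W)
        dW[:D] = X.reshape(B * T, D).T @ dZ.reshape(B * T, 4 * H)
        for t in range(1, T):
            dW[D:] += Hs[:, t - 1].T @ dZ[:, t]
        db = dZ.sum(axis=(0, 1))
        dX = (dZ.reshape(B * T, 4 * H) @ W[:D].T).reshape(B, T, D)
        return dX, dW, db

    def _head_forward(self, hT: np.ndarray, drop_mask: np.ndarray | None):
        a = hT @ self.Wd + self.bd
        d = np.maximum(a, 0.0)
        d_used = d if drop_mask is None else d * drop_mask
        logits = d_used @ self.Wo + self.bo
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, (hT, a, d, d_used)

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities for a standardised batch (B, T, n_mels)."""
        out = X
        for layer in self.lstm:
            out, _ = self._lstm_forward(out, layer)
        probs, _ = self._head_forward(out[:, -1], None)
        return probs

    def _standardise(self, X: np.ndarray) -> np.ndarray:
        return ((X - self.feat_mean) / self.feat_std).astype(np.float32)

    def predict_proba(self, spectrograms: list[LogMelSpectrogram]) -> np.ndarray:
        """p(cough) for each spectrogram; dropout disabled."""
        X = _stack([s.values for s in spectrograms], self.n_mels)
        return self.forward(self._standardise(X))[:, 1]


def _stack(mats: list[np.ndarray], n_mels: int) -> np.ndarray:
    X = np.stack([np.asarray(m, dtype=np.float32) for m in mats])
    if X.ndim != 3 or X.shape[2] != n_mels:
        raise ValueError(f"expected (n, frames, {n_mels}) features, got {X.shape}")
    return X


def build_model(config: ClassifierConfig, mel_params: MelParams | None = None) -> CoughClassifier:
    """Initialise the network deterministically from ``config.seed``."""
    mel_params = mel_params or MelParams()
    return CoughClassifier(config, n_mels=mel_params.n_mels, mel_params=mel_params)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + eps)


def _batch_loss_and_grads(model: CoughClassifier, X, y, w, drop_mask):
    caches = []
    out = X
    for layer in model.lstm:
        out, cache = model._lstm_forward(out, layer)
        caches.append(cache)
    hT = out[:, -1]
    probs, (hT, a, d, d_used) = model._head_forward(hT, drop_mask)
    B = len(y)
    wsum = w.sum()
    loss = float(-(w * np.log(probs[np.arange(B), y] + 1e-12)).sum() / wsum)

    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits *= (w / wsum)[:, None]
    dWo = d_used.T @ dlogits
    dbo = dlogits.sum(axis=0)
    dd = dlogits @ model.Wo.T
    if drop_mask is not None:
        dd = dd * drop_mask
    dd = dd * (a > 0)
    dWd = hT.T @ dd
    dbd = dd.sum(axis=0)
    dhT = dd @ model.Wd.T

    grads: list[np.ndarray] = []
    T = X.shape[1]
    dHs = np.zeros_like(out)
    dHs[:, -1] = dhT
    dIn = dHs
    lstm_grads = []
    for layer, cache in zip(reversed(model.lstm), reversed(caches)):
        dIn, dW, db = model._lstm_backward(dIn, layer, cache)
        lstm_grads.append((dW, db))
    for dW, db in reversed(lstm_grads):
        grads += [dW, db]
    grads += [dWd, dbd, dWo, dbo]
    return loss, grads


def _clip(grads: list[np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads))
    if total > max_norm:
        scale = np.float32(max_norm / total)
        for g in grads:
            g *= scale


def _eval_loss(model: CoughClassifier, X, y, w) -> float:
    probs = model.forward(X)
    return float(-(w * np.log(probs[np.arange(len(y)), y] + 1e-12)).sum() / w.sum())


def train(
    model: CoughClassifier,
    data: list[LabeledExample],
    config: ClassifierConfig | None = None,
) -> list[dict]:
    """Fit the model in place; returns the per-epoch training log.

    Minimises inverse-frequency-weighted cross-entropy with Adam; dropout is
    active only here.  A fraction of the data is held out for early stopping
    on its loss, and the best-epoch weights are restored at the end.  Fully
    reproducible given ``config.seed``.

    Raises
    ------
    ValueError
        If ``data`` does not contain both classes.
    """
    config = config or model.config
    tp = config.train_params
    y = np.array([LABELS.index(ex.label) for ex in data])
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both cough and non_cough examples")

    X_all = _stack([ex.spectrogram.values for ex in data], model.n_mels)
    # standardise per mel band over all frames of the training set
    flat = X_all.reshape(-1, model.n_mels)
    model.feat_mean = flat.mean(axis=0).astype(np.float32)
    model.feat_std = np.maximum(flat.std(axis=0), 1e-6).astype(np.float32)
    X_all = model._standardise(X_all)

    counts = np.bincount(y, minlength=2)
    class_w = (len(y) / (2.0 * np.maximum(counts, 1))).astype(np.float32)
    w_all = class_w[y]

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    # stratified early-stopping holdout
    val_idx: list[int] = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(y == cls)
        rng.shuffle(cls_idx)
        n_val = int(round(tp.val_fraction * len(cls_idx)))
        if len(cls_idx) > 1:
            n_val = min(max(n_val, 1), len(cls_idx) - 1)
        else:
            n_val = 0
        val_idx += list(cls_idx[:n_val])
    val_mask = np.zeros(len(y), dtype=bool)
    val_mask[val_idx] = True
    tr = np.flatnonzero(~val_mask)
    va = np.flatnonzero(val_mask)
    monitor_val = len(va) > 0

    opt = _Adam(model.parameters(), tp.learning_rate)
    drop_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    p_drop = config.dropout_p
    keep = 1.0 - p_drop

    best_loss = np.inf
    best_weights = None
    best_epoch = -1
    stall = 0
    log: list[dict] = []
    for epoch in range(tp.max_epochs):
        order = tr.copy()
        rng.shuffle(order)
        epoch_loss, n_batches = 0.0, 0
        for s in range(0, len(order), tp.batch_size):
            idx = order[s : s + tp.batch_size]
            mask = None
            if p_drop > 0:
                mask = (
                    drop_rng.random((len(idx), model.config.fc_units)) >= p_drop
                ).astype(np.float32) / keep
            loss, grads = _batch_loss_and_grads(model, X_all[idx], y[idx], w_all[idx], mask)
            _clip(grads, tp.grad_clip)
            opt.step(model.parameters(), grads)
            epoch_loss += loss
            n_batches += 1
        train_loss = epoch_loss / max(n_batches, 1)
        if monitor_val:
            stop_loss = _eval_loss(model, X_all[va], y[va], w_all[va])
        else:
            stop_loss = train_loss
        log.append({"epoch": epoch, "train_loss": train_loss, "val_loss": stop_loss})
        if stop_loss < best_loss - 1e-5:
            best_loss = stop_loss
            best_weights = [p.copy() for p in model.parameters()]
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall > tp.patience:
                break
    if best_weights is not None:
        for p, bw in zip(model.parameters(), best_weights):
            p[...] = bw
    model.trained = True
    log.append({"epoch": best_epoch, "train_loss": np.nan, "val_loss": best_loss, "restored": True})
    return log


def predict(
    model: CoughClassifier,
    spectrogram: LogMelSpectrogram,
    threshold: float = 0.5,
    segment_ref: tuple[str, float] = ("", 0.0),
) -> Prediction:
    """Classify one spectrogram; dropout disabled, deterministic.

    The label is ``cough`` iff ``p_cough >= threshold`` — ties go to cough,
    favouring sensitivity.
    """
    if spectrogram.values.shape[1] != model.n_mels:
        raise ValueError(
            f"feature mismatch: model expects {model.n_mels} mel bands, "
            f"got {spectrogram.values.shape[1]}"
        )
    p = float(model.predict_proba([spectrogram])[0])
    return Prediction(
        segment_ref=segment_ref,
        p_cough=p,
        label="cough" if p >= threshold else "non_cough",
    )


# -- persistence -------------------------------------------------------------

_BUNDLE_VERSION = 1


def save_model(model: CoughClassifier, path: str | Path) -> None:
    """Serialise architecture + weights + feature contract into one .npz bundle."""
    cfg = model.config
    header = {
        "version": _BUNDLE_VERSION,
        "config": {
            "lstm_layers": cfg.lstm_layers,
            "lstm_units": cfg.lstm_units,
            "fc_units": cfg.fc_units,
            "dropout_p": cfg.dropout_p,
            "n_classes": cfg.n_classes,
            "seed": cfg.seed,
        },
        "mel_params": model.mel_params.to_dict(),
        "trained": model.trained,
    }
    arrays = {"feat_mean": model.feat_mean, "feat_std": model.feat_std}
    for k, layer in enumerate(model.lstm):
        arrays[f"lstm{k}_W"] = layer["W"]
        arrays[f"lstm{k}_b"] = layer["b"]
    arrays.update(Wd=model.Wd, bd=model.bd, Wo=model.Wo, bo=model.bo)
    np.savez(str(path), header=json.dumps(header), **arrays)


def load_model(path: str | Path) -> CoughClassifier:
    """Load a bundle written by :func:`save_model`."""
    with np.load(str(path), allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        if header["version"] != _BUNDLE_VERSION:
            raise ValueError(f"unsupported model bundle version {header['version']}")
        mel_params = MelParams(**header["mel_params"])
        config = ClassifierConfig(**header["config"])
        model = build_model(config, mel_params)
        for k in range(config.lstm_layers):
            model.lstm[k]["W"] = z[f"lstm{k}_W"]
            model.lstm[k]["b"] = z[f"lstm{k}_b"]
        model.Wd, model.bd = z["Wd"], z["bd"]
        model.Wo, model.bo = z["Wo"], z["bo"]
        model.feat_mean, model.feat_std = z["feat_mean"], z["feat_std"]
        model.trained = bool(header["trained"])
    return model
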