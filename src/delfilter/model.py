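"""A small 1-D convolutional network for filtering deletion candidates.

The classifier treats each normalized 49-feature vector as a 1x49 "image".
The default architecture is one convolution block followed by two fully
connected layers (conv + pool + hidden + output): 8 feature maps with a 1x4
filter at stride 1, max-pooling of width 2, a 32-unit hidden layer, a single
logistic output unit, and dropout (rate 0.3) on the hidden layer.  Deeper
variants (conv+pool stacked two or three times) are available through
:class:`CNNArchitecture`.  Training is plain mini-batch stochastic gradient
descent, theta <- theta - alpha * grad(J), on the mean binary cross-entropy,
with a held-out validation slice and early stopping when validation error
stops improving.  The forward and backward passes are written out explicitly
in numpy so every gradient can be checked against finite differences.

All stochasticity (initialisation, epoch shuffling, dropout masks, the
validation split) flows from a single integer seed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# activations

def activation(x: np.ndarray, kind: str) -> np.ndarray:
    """tanh(x) = (e^x - e^-x)/(e^x + e^-x); relu(x) = max(0, x);
    softplus(x) = log(1 + e^x), computed overflow-safely."""
    x = np.asarray(x, dtype=float)
    if kind == "tanh":
        return np.tanh(x)
    if kind == "relu":
        return np.maximum(0.0, x)
    if kind == "softplus":
        return np.logaddexp(0.0, x)
    raise ValueError(f"unknown activation {kind!r}")


def activation_grad(x: np.ndarray, kind: str) -> np.ndarray:
    """Derivative of :func:`activation` with respect to its input."""
    x = np.asarray(x, dtype=float)
    if kind == "tanh":
        t = np.tanh(x)
        return 1.0 - t * t
    if kind == "relu":
        return (x > 0).astype(float)
    if kind == "softplus":
        return _sigmoid(x)
    raise ValueError(f"unknown activation {kind!r}")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# architecture

@dataclass
class CNNArchitecture:
    """Layer structure: conv blocks, then a hidden layer, then one logistic
    output unit."""

    input_width: int = 49
    conv_blocks: tuple[tuple[int, int, int], ...] = ((8, 4, 1),)  # (maps, width, stride)
    pool_width: int = 2
    pool_mode: str = "max"  # max | mean
    hidden_width: int = 32
    activation: str = "tanh"  # tanh | relu | softplus
    dropout_rate: float = 0.3

    def validate(self) -> None:
        if not self.conv_blocks:
            raise ValueError("need at least one conv+pool block")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.pool_mode not in ("max", "mean"):
            raise ValueError("pool_mode must be 'max' or 'mean'")
        activation(0.0, self.activation)  # raises on bad name
        self.layer_widths()  # raises if a filter is too wide

    def layer_widths(self) -> list[tuple[int, int]]:
        """(width after conv, width after pool) per block."""
        widths = []
        w = self.input_width
        for maps, fw, stride in self.conv_blocks:
            if fw > w:
                raise ValueError(f"filter width {fw} exceeds input width {w}")
            w = (w - fw) // stride + 1
            wc = w
            w = w // self.pool_width
            if w < 1:
                raise ValueError("pooling collapsed the layer to zero width")
            widths.append((wc, w))
        return widths

    @property
    def flat_width(self) -> int:
        return self.conv_blocks[-1][0] * self.layer_widths()[-1][1]


@dataclass
class TrainConfig:
    learning_rate: float = 0.1
    batch_size: int = 64
    max_epochs: int = 100
    early_stop_patience: int = 3
    # validation loss is noisy before the network settles; the stop rule
    # only starts counting after this many epochs
    early_stop_min_epochs: int = 20
    validation_fraction: float = 0.2
    shuffle_each_epoch: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")


# ---------------------------------------------------------------------------
# model

class TrainedModel:
    """Architecture + weights + normalization statistics + training history."""

    def __init__(self, architecture: CNNArchitecture, params: dict[str, np.ndarray],
                 normalizer=None, history: list | None = None, seed: int | None = None):
        self.architecture = architecture
        self.params = params
        self.normalizer = normalizer
        self.history = history or []
        self.seed = seed

    # -- forward -----------------------------------------------------------

    def forward(self, X: np.ndarray, dropout_rng: np.random.Generator | None = None):
        """Forward pass.  Returns (probabilities, cache for backprop).

        Dropout is applied only when ``dropout_rng`` is given (training).
        """
        arch = self.architecture
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != arch.input_width:
            raise ValueError(
                f"expected {arch.input_width} features, got {X.shape[1]}")
        a = X[:, None, :]  # (B, channels=1, width)
        cache = {"inputs": [], "pre": [], "pool_arg": []}
        for bi, (maps, fw, stride) in enumerate(arch.conv_blocks):
            cols = _im2col(a, fw, stride)            # (B, C*fw, T)
            W = self.params[f"conv{bi}_W"]           # (M, C, fw)
            b = self.params[f"conv{bi}_b"]
            z = np.einsum("mk,bkt->bmt", W.reshape(maps, -1), cols) + b[None, :, None]
            h = activation(z, arch.activation)
            pooled, arg = _pool(h, arch.pool_width, arch.pool_mode)
            cache["inputs"].append((a, cols))
            cache["pre"].append(z)
            cache["pool_arg"].append(arg)
            a = pooled
        flat = a.reshape(a.shape[0], -1)
        zh = flat @ self.params["dense_W"].T + self.params["dense_b"]
        ah = activation(zh, arch.activation)
        if dropout_rng is not None and arch.dropout_rate > 0:
            keep = 1.0 - arch.dropout_rate
            mask = (dropout_rng.random(ah.shape) < keep) / keep
        else:
            mask = np.ones_like(ah)
        ad = ah * mask
        zo = ad @ self.params["out_w"] + self.params["out_b"]
        p = _sigmoid(zo)
        cache.update(flat=flat, zh=zh, ah=ah, mask=mask, ad=ad, zo=zo,
                     pooled_shape=a.shape)
        return p, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p, _ = self.forward(X)
        return p

    def predict(self, X: np.ndarray, threshold: float = 0.5
                ) -> tuple[np.ndarray, np.ndarray]:
        """Probabilities and binary calls (1 iff p >= threshold)."""
        p = self.predict_proba(X)
        return p, (p >= threshold).astype(int)

    # -- loss and gradients -------------------------------------------------

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        p, _ = self.forward(X)
        return float(_bce(p, np.asarray(y, dtype=float)))

    def loss_grads(self, X: np.ndarray, y: np.ndarray,
                   dropout_rng: np.random.Generator | None = None
                   ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean binary cross-entropy and its gradient in every parameter."""
        arch = self.architecture
        y = np.asarray(y, dtype=float)
        p, cache = self.forward(X, dropout_rng=dropout_rng)
        B = len(y)
        loss = _bce(p, y)
        grads: dict[str, np.ndarray] = {}

        dzo = (p - y) / B                       # d loss / d zo, shape (B,)
        grads["out_w"] = cache["ad"].T @ dzo
        grads["out_b"] = np.array(dzo.sum())
        dad = dzo[:, None] * self.params["out_w"][None, :]
        dah = dad * cache["mask"]
        dzh = dah * activation_grad(cache["zh"], arch.activation)
        grads["dense_W"] = dzh.T @ cache["flat"]
        grads["dense_b"] = dzh.sum(axis=0)
        da = (dzh @ self.params["dense_W"]).reshape(cache["pooled_shape"])

        for bi in reversed(range(len(arch.conv_blocks))):
            maps, fw, stride = arch.conv_blocks[bi]
            a_in, cols = cache["inputs"][bi]
            z = cache["pre"][bi]
            arg = cache["pool_arg"][bi]
            dh = _unpool(da, arg, z.shape, arch.pool_width, arch.pool_mode)
            dz = dh * activation_grad(z, arch.activation)
            W = self.params[f"conv{bi}_W"]
            grads[f"conv{bi}_W"] = np.einsum("bmt,bkt->mk", dz, cols).reshape(W.shape)
            grads[f"conv{bi}_b"] = dz.sum(axis=(0, 2))
            if bi > 0:
                dcols = np.einsum("mk,bmt->bkt", W.reshape(maps, -1), dz)
                da = _col2im(dcols, a_in.shape, fw, stride)
        return float(loss), grads

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "architecture": asdict(self.architecture),
            "seed": self.seed,
            "normalizer": self.normalizer.to_dict() if self.normalizer else None,
        }
        (path / "model.json").write_text(json.dumps(meta, indent=1))
        np.savez(path / "weights.npz", **self.params)
        if self.history:
            pd.DataFrame(self.history).to_csv(path / "history.tsv", sep="\t",
                                              index=False)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        from .features import Normalizer

        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        arch_d = meta["architecture"]
        arch_d["conv_blocks"] = tuple(tuple(b) for b in arch_d["conv_blocks"])
        arch = CNNArchitecture(**arch_d)
        with np.load(path / "weights.npz") as z:
            params = {k: z[k] for k in z.files}
        norm = (Normalizer.from_dict(meta["normalizer"])
                if meta.get("normalizer") else None)
        hist_path = path / "history.tsv"
        history = (pd.read_csv(hist_path, sep="\t").to_dict("records")
                   if hist_path.exists() else [])
        return cls(arch, params, normalizer=norm, history=history,
                   seed=meta.get("seed"))


# ---------------------------------------------------------------------------
# conv/pool plumbing

def _im2col(a: np.ndarray, fw: int, stride: int) -> np.ndarray:
    """(B, C, W) -> (B, C*fw, T) with T = (W - fw)//stride + 1."""
    B, C, W = a.shape
    T = (W - fw) // stride + 1
    idx = np.arange(fw)[None, :] + stride * np.arange(T)[:, None]  # (T, fw)
    cols = a[:, :, idx]                      # (B, C, T, fw)
    return cols.transpose(0, 1, 3, 2).reshape(B, C * fw, T)


def _col2im(dcols: np.ndarray, a_shape: tuple, fw: int, stride: int) -> np.ndarray:
    B, C, W = a_shape
    T = dcols.shape[2]
    da = np.zeros((B, C, W))
    d = dcols.reshape(B, C, fw, T)
    for f in range(fw):
        pos = f + stride * np.arange(T)
        np.add.at(da, (slice(None), slice(None), pos), d[:, :, f, :])
    return da


def _pool(h: np.ndarray, width: int, mode: str) -> tuple[np.ndarray, np.ndarray | None]:
    B, M, W = h.shape
    T = W // width
    win = h[:, :, :T * width].reshape(B, M, T, width)
    if mode == "max":
        arg = win.argmax(axis=3)
        return win.max(axis=3), arg
    return win.mean(axis=3), None


def _unpool(da: np.ndarray, arg: np.ndarray | None, z_shape: tuple,
            width: int, mode: str) -> np.ndarray:
    B, M, W = z_shape
    T = W // width
    dh = np.zeros(z_shape)
    view = dh[:, :, :T * width].reshape(B, M, T, width)
    if mode == "max":
        bi, mi, ti = np.ogrid[:B, :M, :T]
        view[bi, mi, ti, arg] = da
    else:
        view += (da / width)[:, :, :, None]
    return dh


def _bce(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


# ---------------------------------------------------------------------------
# construction and training

def build_model(architecture: CNNArchitecture | None = None, seed: int = 0,
                normalizer=None) -> TrainedModel:
    """Initialise weights with a symmetric scaled-uniform (Glorot) scheme."""
    arch = architecture or CNNArchitecture()
    arch.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    params: dict[str, np.ndarray] = {}
    channels = 1
    for bi, (maps, fw, stride) in enumerate(arch.conv_blocks):
        fan_in, fan_out = channels * fw, maps * fw
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        params[f"conv{bi}_W"] = rng.uniform(-lim, lim, size=(maps, channels, fw))
        params[f"conv{bi}_b"] = np.zeros(maps)
        channels = maps
    flat = arch.flat_width
    lim = np.sqrt(6.0 / (flat + arch.hidden_width))
    params["dense_W"] = rng.uniform(-lim, lim, size=(arch.hidden_width, flat))
    params["dense_b"] = np.zeros(arch.hidden_width)
    lim = np.sqrt(6.0 / (arch.hidden_width + 1))
    params["out_w"] = rng.uniform(-lim, lim, size=arch.hidden_width)
    params["out_b"] = np.array(0.0)
    return TrainedModel(arch, params, normalizer=normalizer, seed=seed)


def train_sgd(model: TrainedModel, X: np.ndarray, y: np.ndarray,
              config: TrainConfig | None = None) -> TrainedModel:
    """Mini-batch SGD with validation-based early stopping.

    A ``validation_fraction`` slice is held out before training.  After each
    epoch the validation loss is compared with its value at the previous
    check; after ``early_stop_patience`` consecutive increases training stops.
    The returned model carries the weights of the best validation checkpoint
    (the final weights when no validation slice is held out).
    """
    cfg = config or TrainConfig()
    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    ss = np.random.SeedSequence(cfg.seed).spawn(3)
    split_rng = np.random.default_rng(ss[0])
    shuffle_rng = np.random.default_rng(ss[1])
    dropout_rng = np.random.default_rng(ss[2])

    n_val = int(round(cfg.validation_fraction * n))
    perm = split_rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xt, yt = X[train_idx], y[train_idx]
    Xv, yv = X[val_idx], y[val_idx]
    n_train = len(yt)
    if cfg.batch_size > n_train:
        raise ValueError(
            f"batch_size {cfg.batch_size} exceeds the {n_train} training examples")

    best_params = copy.deepcopy(model.params)
    best_val = np.inf
    prev_val = np.inf
    bad_checks = 0
    history = []
    for epoch in range(cfg.max_epochs):
        order = (shuffle_rng.permutation(n_train) if cfg.shuffle_each_epoch
                 else np.arange(n_train))
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, n_train, cfg.batch_size):
            bidx = order[lo:lo + cfg.batch_size]
            loss, grads = model.loss_grads(
                Xt[bidx], yt[bidx],
                dropout_rng=dropout_rng if model.architecture.dropout_rate else None)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"lr={cfg.learning_rate}, batch={cfg.batch_size}")
            for k, g in grads.items():
                model.params[k] = model.params[k] - cfg.learning_rate * g
            epoch_loss += loss
            n_batches += 1
        record = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
        if n_val:
            val_loss = model.loss(Xv, yv)
            record["val_loss"] = val_loss
            if val_loss < best_val:
                best_val = val_loss
                best_params = copy.deepcopy(model.params)
            bad_checks = bad_checks + 1 if val_loss > prev_val else 0
            prev_val = val_loss
            history.append(record)
            if (epoch + 1 >= cfg.early_stop_min_epochs
                    and bad_checks >= cfg.early_stop_patience):
                break
        else:
            history.append(record)
    if n_val:
        model.params = best_params
    model.history = history
    return model


# ---------------------------------------------------------------------------
# grid search

DEFAULT_LR_GRID = (0.1, 0.05, 0.03, 0.01, 0.005)
DEFAULT_BATCH_GRID = (1, 8, 64, 128, 256, 512, 1024, 2048, 4096, 8192)


def grid_search(X: np.ndarray, y: np.ndarray,
                lr_grid: Sequence[float] = DEFAULT_LR_GRID,
                batch_grid: Sequence[int] = DEFAULT_BATCH_GRID,
                replicates: int = 1,
                architecture: CNNArchitecture | None = None,
                train_config: TrainConfig | None = None,
                seed: int = 0) -> pd.DataFrame:
    """Train/evaluate the model at every (learning rate, batch) grid cell.

    Batch values above the training-set size are capped at it (full-batch
    gradient descent).  Each cell reports mean precision ("accuracy"),
    sensitivity and F-score over ``replicates`` seeded runs plus a mortality
    count: runs whose final training accuracy is no better than always
    predicting the majority class.
    """
    from .evaluate import confusion_from_labels, metrics
    from .labeling import split_indices

    base = train_config or TrainConfig()
    rows = []
    for lr in lr_grid:
        for batch in batch_grid:
            accs, sens, fs, deaths = [], [], [], 0
            for rep in range(replicates):
                rep_seed = (seed * 1009 + rep * 131 + hash((lr, batch)) % 1000) % (2**31)
                tr, te = split_indices(len(y), 2 / 3, seed=rep_seed)
                eff_batch = min(batch, max(1, len(tr) - int(
                    round(base.validation_fraction * len(tr)))))
                cfg = TrainConfig(
                    learning_rate=lr, batch_size=eff_batch,
                    max_epochs=base.max_epochs,
                    early_stop_patience=base.early_stop_patience,
                    validation_fraction=base.validation_fraction,
                    shuffle_each_epoch=base.shuffle_each_epoch, seed=rep_seed)
                m = build_model(architecture, seed=rep_seed)
                m = train_sgd(m, X[tr], y[tr], cfg)
                _, train_calls = m.predict(X[tr])
                majority = max(y[tr].mean(), 1 - y[tr].mean())
                if (train_calls == y[tr]).mean() <= majority:
                    deaths += 1
                _, calls = m.predict(X[te])
                mm = metrics(confusion_from_labels(y[te], calls))
                accs.append(mm.accuracy)
                sens.append(mm.sensitivity)
                fs.append(mm.f_score)
            rows.append({
                "learning_rate": lr, "batch_size": batch,
                "accuracy": float(np.mean(accs)),
                "sensitivity": float(np.mean(sens)),
                "f_score": float(np.mean(fs)),
                "mortality": deaths, "replicates": replicates,
            })
    return pd.DataFrame(rows)
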