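"""Patch classifier: a small convolutional network in pure numpy.

Architecture (defaults): conv-conv-pool-conv-conv-pool-dense(512)-dense(4),
ReLU activations, 2x2 max pooling, valid convolutions, dropout on the
hidden dense layer. Trained with plain mini-batch SGD (optional momentum),
Xavier (Glorot uniform) initialization and L2 weight decay. All randomness
(init, shuffling, dropout) flows from one seed in the config.

Implemented directly in numpy because the execution environment provides
no deep-learning framework; convolutions use im2col + matrix products.

Serialization: ``.npz`` archive holding every parameter array, the JSON
config and a format version (see ``PatchClassifier.save``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ClassifierConfig", "PatchClassifier", "train_classifier", "CLASS_NAMES"]

#: Fixed class order; argmax ties resolve to the earliest entry.
CLASS_NAMES = ("nucleus", "nucleus_border", "cytoplasm", "background")

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyper-parameters of the patch classifier.

    Defaults follow the reference training setup (four conv layers split by
    two max-pool layers, dense 512 -> 4, SGD, lr 1e-4, weight decay 1e-6,
    batch 256, 20 epochs); kernel sizes and filter counts are free choices
    exposed here.
    """

    patch_size: int = 43
    conv_channels: tuple[int, ...] = (32, 32, 64, 64)
    kernel_size: int = 3
    pool_after: tuple[int, ...] = (1, 3)  # indices into conv_channels
    dense_units: int = 512
    n_classes: int = 4
    dropout: float = 0.5
    learning_rate: float = 1e-4
    weight_decay: float = 1e-6
    momentum: float = 0.0
    batch_size: int = 256
    epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size % 2 == 0 or self.patch_size < self.kernel_size:
            raise ValueError("patch size must be odd and >= kernel size")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid training parameters")
        if self.n_classes != len(CLASS_NAMES):
            raise ValueError(f"classifier is {len(CLASS_NAMES)}-class")


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H', W', C*k*k) patch matrix for valid conv."""
    v = sliding_window_view(x, (k, k), axis=(2, 3))  # (N, C, H', W', k, k)
    n, c, hh, ww = v.shape[:4]
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, hh, ww, c * k * k
    )


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    n, c, h, w = x_shape
    hh, ww = dcols.shape[1], dcols.shape[2]
    d = dcols.reshape(n, hh, ww, c, k, k)
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + hh, j : j + ww] += d[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dx


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class PatchClassifier:
    """Trained (or freshly initialized) patch classifier.

    Optionally carries the per-position standardization statistics used on
    its training patches, so prediction standardizes identically.
    """

    def __init__(self, config: ClassifierConfig,
                 rng: np.random.Generator | None = None) -> None:
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        k = config.kernel_size
        self.params: dict[str, np.ndarray] = {}
        self.stats_mean: np.ndarray | None = None
        self.stats_std: np.ndarray | None = None

        c_in = 1
        size = config.patch_size
        for i, c_out in enumerate(config.conv_channels):
            fan_in = c_in * k * k
            self.params[f"Wc{i}"] = _glorot(rng, fan_in, c_out * k * k,
                                            (fan_in, c_out))
            self.params[f"bc{i}"] = np.zeros(c_out, dtype=np.float32)
            size = size - k + 1
            if i in config.pool_after:
                size //= 2
            c_in = c_out
        if size < 1:
            raise ValueError("patch size too small for this architecture")
        self._flat = c_in * size * size
        self.params["Wd0"] = _glorot(rng, self._flat, config.dense_units,
                                     (self._flat, config.dense_units))
        self.params["bd0"] = np.zeros(config.dense_units, dtype=np.float32)
        self.params["Wd1"] = _glorot(rng, config.dense_units, config.n_classes,
                                     (config.dense_units, config.n_classes))
        self.params["bd1"] = np.zeros(config.n_classes, dtype=np.float32)

    # ---------------------------------------------------------------- forward
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Forward pass. ``x``: (N, s, s) standardized patches.

        Returns (probabilities, cache); the cache is None unless training.
        """
        cfg = self.config
        k = cfg.kernel_size
        a = np.asarray(x, dtype=np.float32)[:, None, :, :]  # (N,1,s,s)
        cache: list = []
        for i in range(len(cfg.conv_channels)):
            cols = _im2col(a, k)
            z = cols @ self.params[f"Wc{i}"] + self.params[f"bc{i}"]
            relu_mask = z > 0
            z = np.where(relu_mask, z, 0.0)
            out = z.transpose(0, 3, 1, 2)  # (N, F, H', W')
            pooled_mask = None
            pre_pool_shape = out.shape
            if i in cfg.pool_after:
                n, c, h, w = out.shape
                h2, w2 = h // 2, w // 2
                v = out[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
                mx = v.max(axis=(3, 5))
                pooled_mask = v == mx[:, :, :, None, :, None]
                out = mx
            if train:
                cache.append((a.shape, cols, relu_mask, pre_pool_shape, pooled_mask))
            a = out
        n = a.shape[0]
        flat = a.reshape(n, -1)
        h1 = flat @ self.params["Wd0"] + self.params["bd0"]
        h1_mask = h1 > 0
        h1 = np.where(h1_mask, h1, 0.0)
        drop_mask = None
        if train and cfg.dropout > 0:
            keep = 1.0 - cfg.dropout
            drop_mask = (rng.random(h1.shape) < keep).astype(np.float32) / keep
            h1 = h1 * drop_mask
        logits = h1 @ self.params["Wd1"] + self.params["bd1"]
        logits = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        probs = expz / expz.sum(axis=1, keepdims=True)
        if not train:
            return probs, None
        cache.append((flat, h1_mask, drop_mask, h1, a.shape))
        return probs, cache

    # --------------------------------------------------------------- backward
    def _gradients(self, probs: np.ndarray, y: np.ndarray, cache) -> dict:
        cfg = self.config
        k = cfg.kernel_size
        n = probs.shape[0]
        grads: dict[str, np.ndarray] = {}
        flat, h1_mask, drop_mask, h1, a_shape = cache[-1]
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads["Wd1"] = h1.T @ dlogits
        grads["bd1"] = dlogits.sum(axis=0)
        dh1 = dlogits @ self.params["Wd1"].T
        if drop_mask is not None:
            dh1 = dh1 * drop_mask
        dh1 = np.where(h1_mask, dh1, 0.0)
        grads["Wd0"] = flat.T @ dh1
        grads["bd0"] = dh1.sum(axis=0)
        da = (dh1 @ self.params["Wd0"].T).reshape(a_shape)
        for i in reversed(range(len(cfg.conv_channels))):
            x_shape, cols, relu_mask, pre_pool_shape, pooled_mask = cache[i]
            if pooled_mask is not None:
                nn, c, h2, w2 = da.shape
                counts = pooled_mask.sum(axis=(3, 5), keepdims=True)
                dv = pooled_mask * (da[:, :, :, None, :, None] / counts)
                dup = np.zeros(pre_pool_shape, dtype=da.dtype)
                dup[:, :, : h2 * 2, : w2 * 2] = dv.reshape(nn, c, h2 * 2, w2 * 2)
                da = dup
            dz = da.transpose(0, 2, 3, 1)  # (N, H', W', F)
            dz = np.where(relu_mask, dz, 0.0)
            grads[f"Wc{i}"] = np.tensordot(cols, dz, axes=([0, 1, 2], [0, 1, 2]))
            grads[f"bc{i}"] = dz.sum(axis=(0, 1, 2))
            da = _col2im(dz @ self.params[f"Wc{i}"].T, x_shape, k)
        return grads

    # -------------------------------------------------------------- inference
    def predict_proba(self, patches: np.ndarray,
                      batch_size: int = 1024) -> np.ndarray:
        """Class probabilities for raw patches (standardized here if the
        model carries position statistics)."""
        patches = np.asarray(patches, dtype=np.float32)
        if patches.ndim == 2:
            patches = patches[None]
        if patches.shape[1:] != (self.config.patch_size, self.config.patch_size):
            raise ValueError(
                f"patch shape {patches.shape[1:]} does not match model "
                f"patch size {self.config.patch_size}"
            )
        if self.stats_mean is not None:
            patches = (patches - self.stats_mean) / self.stats_std
        out = np.empty((patches.shape[0], self.config.n_classes), dtype=np.float32)
        for start in range(0, patches.shape[0], batch_size):
            chunk = patches[start : start + batch_size]
            out[start : start + chunk.shape[0]], _ = self.forward(chunk)
        return out

    def set_stats(self, mean: np.ndarray, std: np.ndarray) -> None:
        if mean.shape != (self.config.patch_size,) * 2:
            raise ValueError("statistics shape must equal the patch size")
        self.stats_mean = np.asarray(mean, dtype=np.float32)
        self.stats_std = np.asarray(std, dtype=np.float32)

    # ----------------------------------------------------------- persistence
    def save(self, path) -> None:
        payload = dict(self.params)
        if self.stats_mean is not None:
            payload["stats_mean"] = self.stats_mean
            payload["stats_std"] = self.stats_std
        cfg = asdict(self.config)
        payload["meta"] = np.frombuffer(
            json.dumps({"format_version": MODEL_FORMAT_VERSION, "config": cfg}).encode(),
            dtype=np.uint8,
        )
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "PatchClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta["format_version"] != MODEL_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported model format version {meta['format_version']}"
                )
            cfg_dict = meta["config"]
            for key in ("conv_channels", "pool_after"):
                cfg_dict[key] = tuple(cfg_dict[key])
            model = cls(ClassifierConfig(**cfg_dict))
            for name in model.params:
                model.params[name] = data[name]
            if "stats_mean" in data:
                model.set_stats(data["stats_mean"], data["stats_std"])
        return model


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


def _accuracy(model: PatchClassifier, x: np.ndarray, y: np.ndarray,
              batch_size: int = 1024) -> float:
    # x is already standardized; bypass the model's stats on purpose
    hits = 0
    for start in range(0, x.shape[0], batch_size):
        probs, _ = model.forward(x[start : start + batch_size])
        hits += int((probs.argmax(axis=1) == y[start : start + batch_size]).sum())
    return hits / x.shape[0]


def train_classifier(
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    config: ClassifierConfig | None = None,
    stats=None,
) -> tuple[PatchClassifier, TrainingHistory]:
    """Train the patch classifier with mini-batch SGD.

    ``train_x``/``val_x`` are (N, s, s) standardized patches and labels are
    class indices in the fixed class order. ``stats`` (a PositionStats) is
    stored on the model so raw patches can be standardized at prediction
    time.
    """
    config = config or ClassifierConfig()
    train_y = np.asarray(train_y)
    val_y = np.asarray(val_y)
    if len(train_x) == 0 or len(val_x) == 0:
        raise ValueError("training and validation sets must be non-empty")
    present = set(np.unique(train_y).tolist())
    missing = [CLASS_NAMES[c] for c in range(config.n_classes) if c not in present]
    if missing:
        raise ValueError(f"classes missing from the training set: {missing}")

    rng = np.random.default_rng(config.seed)
    model = PatchClassifier(config, rng=rng)
    if stats is not None:
        model.set_stats(stats.mean, stats.std)
    history = TrainingHistory()
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    x = np.asarray(train_x, dtype=np.float32)
    n = x.shape[0]
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], train_y[idx]
            probs, cache = model.forward(xb, train=True, rng=rng)
            eps = 1e-12
            epoch_loss += float(
                -np.log(probs[np.arange(len(yb)), yb] + eps).mean()
            )
            n_batches += 1
            grads = model._gradients(probs, yb, cache)
            for name, g in grads.items():
                g = g + config.weight_decay * model.params[name]
                if config.momentum > 0:
                    velocity[name] = config.momentum * velocity[name] - config.learning_rate * g
                    model.params[name] += velocity[name].astype(np.float32)
                else:
                    model.params[name] -= (config.learning_rate * g).astype(np.float32)
        history.train_loss.append(epoch_loss / max(n_batches, 1))
        history.val_accuracy.append(
            _accuracy(model, np.asarray(val_x, dtype=np.float32), val_y)
        )
    if config.epochs == 0:
        warnings.warn("epochs=0: returning an untrained model", stacklevel=2)
    return model, history
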