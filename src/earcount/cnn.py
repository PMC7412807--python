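"""Four-class convolutional ear-patch classifier.

Architecture: five 3x3 convolution + ReLU + 2x2 max-pool blocks followed by
two fully connected layers and a softmax over the four ear-count classes
(0/1/2/3).  Convolutions use same-padding; pooling uses stride-2 floor
division, so a 100x100 input shrinks 100 -> 50 -> 25 -> 12 -> 6 -> 3 and the
first dense layer sees 3*3*C5 features.  Training minimizes softmax
cross-entropy with Adam on mini-batches.

The network is small enough that the forward and backward passes are
written directly in NumPy (im2col + BLAS matrix products), which keeps the
package dependency-light and the arithmetic bit-reproducible for a fixed
seed on a fixed platform.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import LabeledPatch, PatchDataset
from .image_prep import resize

__all__ = [
    "CnnConfig",
    "TrainConfig",
    "ModelState",
    "build_model",
    "train",
    "predict",
    "evaluate_classifier",
    "parameter_count",
    "save_model",
    "load_model",
]

_KERNEL = 3  # fixed 3x3 convolution kernels
_N_CONV = 5  # fixed depth: five conv + five pool blocks


@dataclass(frozen=True)
class CnnConfig:
    """Network hyperparameters.

    Exactly five conv blocks (3x3 kernels, ReLU, 2x2 max-pool) and two fully
    connected layers; the final layer has 4 units (the ear-count classes).
    Channel widths and the hidden dense width are free parameters.
    """

    conv_channels: tuple[int, ...] = (16, 32, 64, 128, 256)
    fc_sizes: tuple[int, int] = (256, 4)
    input_hw: tuple[int, int] = (100, 100)
    n_classes: int = 4

    def __post_init__(self) -> None:
        if len(self.conv_channels) != _N_CONV:
            raise ValueError(
                f"architecture is fixed at {_N_CONV} conv layers, "
                f"got {len(self.conv_channels)}"
            )
        if len(self.fc_sizes) != 2 or self.fc_sizes[-1] != self.n_classes:
            raise ValueError(
                f"need two fully connected layers ending in {self.n_classes} units"
            )
        if min(self.conv_channels) < 1 or min(self.fc_sizes) < 1:
            raise ValueError("layer widths must be positive")

    def spatial_sizes(self) -> list[tuple[int, int]]:
        """Feature-map sizes after each pool (floor division by 2)."""
        h, w = self.input_hw
        sizes = []
        for _ in range(_N_CONV):
            h, w = h // 2, w // 2
            sizes.append((h, w))
        return sizes

    def flat_features(self) -> int:
        h, w = self.spatial_sizes()[-1]
        return h * w * self.conv_channels[-1]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    ``steps`` counts mini-batch gradient iterations when ``epochs_mode`` is
    "steps" (the default), or full passes over the training set when it is
    "passes".
    """

    steps: int = 8000
    batch_size: int = 64
    learning_rate: float = 1e-4
    lr_decay: str = "constant"  # or "cosine": anneal to 0 over the run
    seed: int = 0
    log_every: int = 50
    epochs_mode: str = "steps"

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs_mode not in ("steps", "passes"):
            raise ValueError("epochs_mode must be 'steps' or 'passes'")
        if self.lr_decay not in ("constant", "cosine"):
            raise ValueError("lr_decay must be 'constant' or 'cosine'")


@dataclass
class ModelState:
    """Architecture + weights + training log."""

    config: CnnConfig
    params: dict[str, np.ndarray]
    training_log: list[dict[str, float]] = field(default_factory=list)


def parameter_count(cfg: CnnConfig) -> int:
    """Total number of trainable scalars (weights + biases)."""
    n = 0
    c_in = 3
    for c_out in cfg.conv_channels:
        n += c_out * c_in * _KERNEL * _KERNEL + c_out
        c_in = c_out
    f_in = cfg.flat_features()
    for f_out in cfg.fc_sizes:
        n += f_in * f_out + f_out
        f_in = f_out
    return n


def build_model(cfg: CnnConfig | None = None, seed: int = 0) -> ModelState:
    """He-normal initialized network; deterministic for a given seed."""
    cfg = cfg or CnnConfig()
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    c_in = 3
    for i, c_out in enumerate(cfg.conv_channels):
        fan_in = c_in * _KERNEL * _KERNEL
        params[f"conv{i}_W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, _KERNEL, _KERNEL)
        ).astype(np.float32)
        params[f"conv{i}_b"] = np.zeros(c_out, dtype=np.float32)
        c_in = c_out
    f_in = cfg.flat_features()
    for i, f_out in enumerate(cfg.fc_sizes):
        params[f"fc{i}_W"] = rng.normal(
            0.0, np.sqrt(2.0 / f_in), size=(f_in, f_out)
        ).astype(np.float32)
        params[f"fc{i}_b"] = np.zeros(f_out, dtype=np.float32)
        f_in = f_out
    return ModelState(config=cfg, params=params)


# ---------------------------------------------------------------- layer math


def _im2col(xp: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """(N, C, H+2, W+2) padded input -> (C*9, N*out_h*out_w) column matrix."""
    n, c = xp.shape[:2]
    cols = np.empty((c, _KERNEL * _KERNEL, n, out_h, out_w), dtype=xp.dtype)
    for ki in range(_KERNEL):
        for kj in range(_KERNEL):
            cols[:, ki * _KERNEL + kj] = xp[
                :, :, ki : ki + out_h, kj : kj + out_w
            ].transpose(1, 0, 2, 3)
    return cols.reshape(c * _KERNEL * _KERNEL, n * out_h * out_w)


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    n, c, h, w = x.shape
    o = W.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = _im2col(xp, h, w)
    y = W.reshape(o, -1) @ cols + b[:, None]
    y = y.reshape(o, n, h, w).transpose(1, 0, 2, 3)
    return y, (cols, x.shape, W)


def _conv_backward(dy: np.ndarray, cache):
    cols, x_shape, W = cache
    n, c, h, w = x_shape
    o = W.shape[0]
    dy_m = dy.transpose(1, 0, 2, 3).reshape(o, -1)
    dW = (dy_m @ cols.T).reshape(W.shape)
    db = dy_m.sum(axis=1)
    dcols = W.reshape(o, -1).T @ dy_m  # (C*9, N*h*w)
    dcols = dcols.reshape(c, _KERNEL * _KERNEL, n, h, w)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dy.dtype)
    for ki in range(_KERNEL):
        for kj in range(_KERNEL):
            dxp[:, :, ki : ki + h, kj : kj + w] += dcols[
                :, ki * _KERNEL + kj
            ].transpose(1, 0, 2, 3)
    return dxp[:, :, 1:-1, 1:-1], dW, db


def _pool_forward(x: np.ndarray):
    n, c, h, w = x.shape
    ph, pw = h // 2, w // 2
    xc = x[:, :, : ph * 2, : pw * 2]
    windows = xc.reshape(n, c, ph, 2, pw, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, ph, pw, 4
    )
    idx = windows.argmax(axis=-1)
    y = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    return y, (x.shape, idx)


def _pool_backward(dy: np.ndarray, cache):
    x_shape, idx = cache
    n, c, h, w = x_shape
    ph, pw = h // 2, w // 2
    dwin = np.zeros((n, c, ph, pw, 4), dtype=dy.dtype)
    np.put_along_axis(dwin, idx[..., None], dy[..., None], axis=-1)
    dx = np.zeros(x_shape, dtype=dy.dtype)
    dx[:, :, : ph * 2, : pw * 2] = (
        dwin.reshape(n, c, ph, pw, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, ph * 2, pw * 2
        )
    )
    return dx


def _forward(model: ModelState, x: np.ndarray, want_cache: bool = False):
    """x: (N, 3, H, W) float32 in [0, 1] -> logits (N, 4) [+ caches]."""
    cfg = model.config
    p = model.params
    caches = []
    a = x
    for i in range(_N_CONV):
        z, conv_cache = _conv_forward(a, p[f"conv{i}_W"], p[f"conv{i}_b"])
        relu_mask = z > 0
        a = z * relu_mask
        a, pool_cache = _pool_forward(a)
        caches.append((conv_cache, relu_mask, pool_cache))
    n = a.shape[0]
    flat = a.reshape(n, -1)
    h1 = flat @ p["fc0_W"] + p["fc0_b"]
    h1_mask = h1 > 0
    h1r = h1 * h1_mask
    logits = h1r @ p["fc1_W"] + p["fc1_b"]
    if not want_cache:
        return logits
    return logits, (caches, flat, h1_mask, h1r, a.shape)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _loss_and_grads(model: ModelState, x: np.ndarray, y: np.ndarray):
    """Mean softmax cross-entropy and parameter gradients for one batch."""
    p = model.params
    logits, (caches, flat, h1_mask, h1r, conv_out_shape) = _forward(
        model, x, want_cache=True
    )
    n = x.shape[0]
    probs = _softmax(logits)
    loss = float(-np.log(probs[np.arange(n), y] + 1e-12).mean())
    acc = float((logits.argmax(axis=1) == y).mean())

    dlogits = probs.astype(np.float32)
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n

    grads: dict[str, np.ndarray] = {}
    grads["fc1_W"] = h1r.T @ dlogits
    grads["fc1_b"] = dlogits.sum(axis=0)
    dh1 = (dlogits @ p["fc1_W"].T) * h1_mask
    grads["fc0_W"] = flat.T @ dh1
    grads["fc0_b"] = dh1.sum(axis=0)
    da = (dh1 @ p["fc0_W"].T).reshape(conv_out_shape)
    for i in range(_N_CONV - 1, -1, -1):
        conv_cache, relu_mask, pool_cache = caches[i]
        dz = _pool_backward(da, pool_cache) * relu_mask
        da, dW, db = _conv_backward(dz, conv_cache)
        grads[f"conv{i}_W"] = dW
        grads[f"conv{i}_b"] = db
    return loss, acc, grads


def _patches_to_batch(patches, input_hw) -> np.ndarray:
    """uint8 HxWx3 patches -> (N, 3, H, W) float32 in [0, 1]."""
    h, w = input_hw
    arrs = []
    for p in patches:
        img = p.patch if isinstance(p, LabeledPatch) else np.asarray(p)
        if img.shape[:2] != (h, w):
            img = resize(img, h, w)
        arrs.append(img)
    x = np.stack(arrs).astype(np.float32) / 255.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def train(
    model: ModelState, data: PatchDataset, cfg: TrainConfig | None = None
) -> ModelState:
    """Adam on mini-batch softmax cross-entropy; returns a new ModelState.

    The input model is not modified.  Batches cycle through seeded random
    permutations of the training set, so runs are reproducible given the
    model seed, data and train seed.
    """
    cfg = cfg or TrainConfig()
    if not data.train:
        raise ValueError("empty training set")
    labels_present = {p.label for p in data.train}
    missing = set(range(model.config.n_classes)) - labels_present
    if missing:
        raise ValueError(f"training set has no examples of classes {sorted(missing)}")

    params = {k: v.copy() for k, v in model.params.items()}
    out = ModelState(
        config=model.config, params=params, training_log=list(model.training_log)
    )
    n = len(data.train)
    steps = cfg.steps
    if cfg.epochs_mode == "passes":
        steps = cfg.steps * int(np.ceil(n / cfg.batch_size))
    if steps == 0:
        return out

    x_all = _patches_to_batch(data.train, model.config.input_hw)
    y_all = np.array([p.label for p in data.train], dtype=np.int64)

    rng = np.random.default_rng(cfg.seed)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(vv) for k, vv in params.items()}
    order = rng.permutation(n)
    cursor = 0
    for step in range(1, steps + 1):
        if cursor + cfg.batch_size > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor : cursor + cfg.batch_size]
        cursor += cfg.batch_size
        loss, acc, grads = _loss_and_grads(out, x_all[idx], y_all[idx])
        lr = cfg.learning_rate
        if cfg.lr_decay == "cosine":
            lr = lr * 0.5 * (1.0 + np.cos(np.pi * (step - 1) / steps))
        lr_t = lr * np.sqrt(1 - beta2**step) / (1 - beta1**step)
        for k, g in grads.items():
            g = g.astype(np.float32)
            m[k] = beta1 * m[k] + (1 - beta1) * g
            v[k] = beta2 * v[k] + (1 - beta2) * g * g
            params[k] -= lr_t * m[k] / (np.sqrt(v[k]) + eps)
        if step % cfg.log_every == 0 or step == 1 or step == steps:
            out.training_log.append(
                {"step": float(step), "loss": loss, "batch_accuracy": acc}
            )
    return out


def predict(
    model: ModelState, patches, batch_size: int = 256
) -> list[tuple[int, np.ndarray]]:
    """Per-patch (label, probability 4-vector); ties go to the lowest class.

    Patches may be LabeledPatch objects or raw HxWx3 arrays; anything not at
    the input size is resized first.
    """
    if len(patches) == 0:
        return []
    results = []
    for i in range(0, len(patches), batch_size):
        x = _patches_to_batch(patches[i : i + batch_size], model.config.input_hw)
        probs = _softmax(_forward(model, x))
        labels = probs.argmax(axis=1)  # argmax returns the lowest tied index
        results.extend((int(l), p.astype(np.float64)) for l, p in zip(labels, probs))
    return results


def evaluate_classifier(model: ModelState, test) -> np.ndarray:
    """4x4 confusion matrix (rows: true class, cols: predicted)."""
    if len(test) == 0:
        raise ValueError("empty test set")
    k = model.config.n_classes
    cm = np.zeros((k, k), dtype=np.int64)
    preds = predict(model, test)
    for p, (pred, _) in zip(test, preds):
        cm[p.label, pred] += 1
    return cm


def save_model(model: ModelState, path: str | Path) -> None:
    """Checkpoint: one zip with architecture JSON + weight arrays (npz)."""
    path = Path(path)
    arch = {
        "conv_channels": list(model.config.conv_channels),
        "fc_sizes": list(model.config.fc_sizes),
        "input_hw": list(model.config.input_hw),
        "n_classes": model.config.n_classes,
        "training_log": model.training_log,
    }
    buf = io.BytesIO()
    np.savez(buf, **model.params)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("architecture.json", json.dumps(arch))
        zf.writestr("weights.npz", buf.getvalue())


def load_model(path: str | Path) -> ModelState:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        arch = json.loads(zf.read("architecture.json"))
        with zf.open("weights.npz") as f:
            npz = np.load(io.BytesIO(f.read()))
            params = {k: npz[k] for k in npz.files}
    cfg = CnnConfig(
        conv_channels=tuple(arch["conv_channels"]),
        fc_sizes=tuple(arch["fc_sizes"]),
        input_hw=tuple(arch["input_hw"]),
        n_classes=arch["n_classes"],
    )
    return ModelState(config=cfg, params=params, training_log=arch["training_log"])
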