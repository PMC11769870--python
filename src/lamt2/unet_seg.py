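"""Trainable 2D U-Net segmentation of bones and cartilages from MESE slices.

A classic encoder--decoder U-Net (two 3x3 convolutions + ReLU per level,
channel doubling, 2x2 max-pooling, 2x2 transposed-convolution upsampling,
skip concatenations, 1x1 softmax head) operating on sagittal slices.  The
all-echo variant takes all 7 echo images as input channels; the first-echo
variant takes 1 channel.  Training uses a weighted cross-entropy loss and
Adam with an initial learning rate of 0.01, mini-batches of 4 slices, and
keeps the parameter set of the epoch with the best mean validation Dice.

The network, its backward pass and the Adam optimiser are implemented
directly in NumPy: convolutions run as im2col matrix products, and the
input-gradient of a convolution is computed as a convolution with the
spatially flipped kernels.  Weights are initialised with a variance-scaling
(He) scheme.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import LabelMask, MESEVolume

__all__ = [
    "UNetConfig",
    "TrainedModel",
    "weighted_xent",
    "train_unet",
    "predict_mask",
    "save_model",
    "load_model",
    "BONE_WEIGHTS",
    "CARTILAGE_WEIGHTS",
]

#: empirically determined label weights of the published method
BONE_WEIGHTS = {"background": 0.2, "femur": 0.25, "tibia": 0.25, "fibula": 0.3}
CARTILAGE_WEIGHTS = {"background": 0.2, "tibial": 0.4, "femoral": 0.4}

_LOG_EPS = 1e-7


@dataclass
class UNetConfig:
    in_channels: int = 7                      # 7 = all-echo, 1 = first-echo
    out_labels: tuple[str, ...] = ("tibial", "femoral")
    label_weights: dict = field(default_factory=lambda: dict(CARTILAGE_WEIGHTS))
    levels: int = 4
    base_filters: int = 32
    learning_rate: float = 0.01
    batch_slices: int = 4
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_channels not in (1, 7):
            raise ValueError("in_channels must be 1 (first echo) or 7 (all echoes)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        missing = [n for n in ("background", *self.out_labels) if n not in self.label_weights]
        if missing:
            raise ValueError(f"label_weights missing entries for {missing}")

    @property
    def n_classes(self) -> int:
        return 1 + len(self.out_labels)

    def weight_vector(self) -> np.ndarray:
        return np.array(
            [self.label_weights["background"]]
            + [self.label_weights[n] for n in self.out_labels],
            dtype=np.float32,
        )


@dataclass
class TrainedModel:
    params: dict
    config: UNetConfig
    history: list              # per-epoch {"train_loss": ..., "val_dsc": ...}
    selected_epoch: int


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def weighted_xent(predicted_probabilities: np.ndarray, target: np.ndarray,
                  weights) -> float:
    """Mean over voxels of ``-w(true class) * log p(true class)``.

    ``predicted_probabilities`` has shape (K, H, W) or (N, K, H, W) with
    per-voxel distributions over K classes; ``target`` holds integer class
    indices.  Probabilities are clamped at 1e-7 so the loss stays finite.
    """
    p = np.asarray(predicted_probabilities, dtype=np.float64)
    t = np.asarray(target)
    if p.ndim == 3:
        p = p[None]
        t = t[None]
    w = np.asarray(weights, dtype=np.float64)
    if t.max() >= p.shape[1]:
        raise ValueError("target contains a class index outside the prediction")
    pt = np.take_along_axis(p, t[:, None], axis=1)[:, 0]
    return float(np.mean(-w[t] * np.log(np.clip(pt, _LOG_EPS, None))))


def _softmax_xent_grad(logits: np.ndarray, target: np.ndarray, w: np.ndarray):
    """Fused stable softmax + weighted CE; returns (loss, dlogits)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n_vox = target.size
    pt = np.take_along_axis(p, target[:, None], axis=1)[:, 0]
    wt = w[target]
    loss = float(np.mean(-wt * np.log(np.clip(pt, _LOG_EPS, None))))
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, target[:, None], 1.0, axis=1)
    dlogits = (wt[:, None] * (p - onehot) / n_vox).astype(logits.dtype)
    return loss, dlogits


# ---------------------------------------------------------------------------
# Layers (im2col convolutions, pooling, transposed convolution)
# ---------------------------------------------------------------------------

def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patches of 3x3 neighbourhoods."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))      # (N, C, H, W, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * 9)


def _conv3_forward(x, wmat, bias):
    n, c, h, w = x.shape
    cols = _im2col3(x)
    y = cols @ wmat + bias
    return y.reshape(n, h, w, -1).transpose(0, 3, 1, 2), cols


def _conv3_backward(dy, x_shape, cols, wmat):
    n, c, h, w = x_shape
    f = wmat.shape[1]
    dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n * h * w, f)
    dwmat = cols.T @ dyf
    dbias = dyf.sum(axis=0)
    # input gradient = convolution of dy with 180deg-flipped kernels
    wk = wmat.reshape(c, 3, 3, f)
    wback = wk[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(f * 9, c)
    dcols = _im2col3(dy)
    dx = (dcols @ wback).reshape(n, h, w, c).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(dx), dwmat, dbias


def _pool2_forward(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    y = xr.max(axis=(3, 5))
    mask = xr == y[:, :, :, None, :, None]
    # break ties: keep only the first maximal element per window
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    first = np.cumsum(flat, axis=-1) == 1
    flat = flat & first
    mask = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return y, mask


def _pool2_backward(dy, mask):
    n, c, hh, _, ww, _ = mask.shape
    dx = mask * dy[:, :, :, None, :, None]
    return dx.reshape(n, c, hh * 2, ww * 2)


def _upconv2_forward(x, wk):
    # wk: (C_in, C_out, 2, 2); output (N, C_out, 2H, 2W)
    y = np.einsum("nchw,cfij->nfhiwj", x, wk, optimize=True)
    n, f, h, _, w, _ = y.shape
    return np.ascontiguousarray(y).reshape(n, f, h * 2, w * 2)


def _upconv2_backward(dy, x, wk):
    n, f, h2, w2 = dy.shape
    dyr = dy.reshape(n, f, h2 // 2, 2, w2 // 2, 2)
    dx = np.einsum("nfhiwj,cfij->nchw", dyr, wk, optimize=True)
    dwk = np.einsum("nchw,nfhiwj->cfij", x, dyr, optimize=True)
    return np.ascontiguousarray(dx), dwk


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class UNet2D:
    """Fully convolutional 2D U-Net over float32 slice batches."""

    def __init__(self, config: UNetConfig, rng: np.random.Generator | None = None,
                 params: dict | None = None):
        self.config = config
        if params is not None:
            self.params = params
        else:
            rng = rng or np.random.default_rng(config.seed)
            self.params = self._init_params(rng)

    def _init_params(self, rng) -> dict:
        cfg = self.config
        params: dict = {}

        def conv(name, cin, cout):
            fan_in = cin * 9
            params[f"{name}_w"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (cin * 9, cout)).astype(np.float32)
            params[f"{name}_b"] = np.zeros(cout, dtype=np.float32)

        cin = cfg.in_channels
        for lvl in range(cfg.levels):
            f = cfg.base_filters * 2**lvl
            conv(f"enc{lvl}a", cin, f)
            conv(f"enc{lvl}b", f, f)
            cin = f
        for lvl in range(cfg.levels - 2, -1, -1):
            f = cfg.base_filters * 2**lvl
            fan_in = cin * 4
            params[f"up{lvl}_w"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (cin, f, 2, 2)).astype(np.float32)
            conv(f"dec{lvl}a", 2 * f, f)
            conv(f"dec{lvl}b", f, f)
            cin = f
        params["head_w"] = rng.normal(
            0.0, np.sqrt(2.0 / cin), (cin, cfg.n_classes)).astype(np.float32)
        params["head_b"] = np.zeros(cfg.n_classes, dtype=np.float32)
        return params

    # -- forward ----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False):
        cfg = self.config
        p = self.params
        cache: dict = {"x": x}
        skips = []
        h = x
        for lvl in range(cfg.levels):
            for sub in "ab":
                name = f"enc{lvl}{sub}"
                y, cols = _conv3_forward(h, p[f"{name}_w"], p[f"{name}_b"])
                r = np.maximum(y, 0.0)
                if train:
                    cache[name] = (h.shape, cols, y > 0)
                h = r
            if lvl < cfg.levels - 1:
                skips.append(h)
                h, mask = _pool2_forward(h)
                if train:
                    cache[f"pool{lvl}"] = mask
        for lvl in range(cfg.levels - 2, -1, -1):
            xin = h
            h = _upconv2_forward(h, p[f"up{lvl}_w"])
            if train:
                cache[f"up{lvl}"] = xin
            skip = skips[lvl]
            h = np.concatenate([skip, h], axis=1)
            for sub in "ab":
                name = f"dec{lvl}{sub}"
                y, cols = _conv3_forward(h, p[f"{name}_w"], p[f"{name}_b"])
                r = np.maximum(y, 0.0)
                if train:
                    cache[name] = (h.shape, cols, y > 0)
                h = r
        # 1x1 head
        n, c, hh, ww = h.shape
        if train:
            cache["head_in"] = h
        logits = np.einsum("nchw,ck->nkhw", h, p["head_w"], optimize=True) \
            + p["head_b"][None, :, None, None]
        return logits, cache

    # -- backward ---------------------------------------------------------
    def backward(self, dlogits: np.ndarray, cache: dict) -> dict:
        cfg = self.config
        p = self.params
        grads: dict = {}
        hin = cache["head_in"]
        grads["head_w"] = np.einsum("nchw,nkhw->ck", hin, dlogits, optimize=True)
        grads["head_b"] = dlogits.sum(axis=(0, 2, 3))
        dh = np.einsum("nkhw,ck->nchw", dlogits, p["head_w"], optimize=True)
        dh = np.ascontiguousarray(dh)
        dskips = {}
        for lvl in range(0, cfg.levels - 1):
            for sub in "ba":
                name = f"dec{lvl}{sub}"
                shape, cols, relu = cache[name]
                dh = dh * relu
                dh, grads[f"{name}_w"], grads[f"{name}_b"] = _conv3_backward(
                    dh, shape, cols, p[f"{name}_w"])
            f = cfg.base_filters * 2**lvl
            dskips[lvl] = dh[:, :f]
            dup = dh[:, f:]
            xin = cache[f"up{lvl}"]
            dh, grads[f"up{lvl}_w"] = _upconv2_backward(dup, xin, p[f"up{lvl}_w"])
        for lvl in range(cfg.levels - 1, -1, -1):
            if lvl < cfg.levels - 1:
                dh = _pool2_backward(dh, cache[f"pool{lvl}"])
                dh = dh + dskips[lvl]
            for sub in "ba":
                name = f"enc{lvl}{sub}"
                shape, cols, relu = cache[name]
                dh = dh * relu
                dh, grads[f"{name}_w"], grads[f"{name}_b"] = _conv3_backward(
                    dh, shape, cols, p[f"{name}_w"])
        return grads


class Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def _volume_channels(volume: MESEVolume, in_channels: int) -> np.ndarray:
    """Select and standardise input channels: per volume, per channel."""
    if in_channels == volume.n_echoes:
        data = volume.intensities
    elif in_channels == 1:
        data = volume.intensities[:1]
    else:
        raise ConfigError(
            f"model expects {in_channels} channels but volume has {volume.n_echoes} echoes"
        )
    data = np.asarray(data, dtype=np.float32)
    mean = data.mean(axis=(1, 2, 3), keepdims=True)
    std = data.std(axis=(1, 2, 3), keepdims=True)
    return (data - mean) / np.where(std > 0, std, 1.0)


def _target_labels(mask: LabelMask, out_labels) -> np.ndarray:
    t = np.zeros(mask.labels.shape, dtype=np.int64)
    for i, name in enumerate(out_labels, start=1):
        if name in mask.label_dict:
            t[mask.labels == mask.label_dict[name]] = i
    return t


def _stack_slices(pairs, config: UNetConfig):
    xs, ys = [], []
    for volume, mask in pairs:
        data = _volume_channels(volume, config.in_channels)
        target = _target_labels(mask, config.out_labels)
        for z in range(data.shape[1]):
            xs.append(data[:, z])
            ys.append(target[z])
    return np.stack(xs).astype(np.float32), np.stack(ys)


def _mean_foreground_dsc(pred: np.ndarray, target: np.ndarray, n_classes: int) -> float:
    """Unweighted mean of per-label Dice over foreground labels."""
    scores = []
    for k in range(1, n_classes):
        a = pred == k
        b = target == k
        denom = a.sum() + b.sum()
        scores.append(1.0 if denom == 0 else 2.0 * (a & b).sum() / denom)
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------

def train_unet(train, val, config: UNetConfig) -> TrainedModel:
    """Train slice-wise over all sagittal slices; checkpoint at best mean
    validation Dice (unweighted over foreground labels, averaged over
    validation volumes)."""
    if not train or not val:
        raise ValueError("need at least one training and one validation volume")
    x_train, y_train = _stack_slices(train, config)
    if not (y_train > 0).any():
        raise ValueError("degenerate training data: no foreground in any slice")
    val_data = [
        (_volume_channels(v, config.in_channels), _target_labels(m, config.out_labels))
        for v, m in val
    ]
    rng = np.random.default_rng(config.seed)
    net = UNet2D(config, rng=rng)
    opt = Adam(net.params, config.learning_rate)
    w = config.weight_vector().astype(np.float32)

    history = []
    best = (-1.0, None, -1)
    n_slices = x_train.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n_slices)
        losses = []
        for start in range(0, n_slices, config.batch_slices):
            idx = order[start:start + config.batch_slices]
            xb, yb = x_train[idx], y_train[idx]
            logits, cache = net.forward(xb, train=True)
            loss, dlogits = _softmax_xent_grad(logits, yb, w)
            grads = net.backward(dlogits, cache)
            opt.step(net.params, grads)
            losses.append(loss)
        val_scores = []
        for data, target in val_data:
            pred = _predict_labels(net, data)
            val_scores.append(_mean_foreground_dsc(pred, target, config.n_classes))
        val_dsc = float(np.mean(val_scores))
        history.append({"train_loss": float(np.mean(losses)), "val_dsc": val_dsc})
        if val_dsc > best[0]:
            best = (val_dsc, {k: v.copy() for k, v in net.params.items()}, epoch)
    return TrainedModel(params=best[1], config=config, history=history,
                        selected_epoch=best[2])


def _predict_labels(net: UNet2D, data: np.ndarray, batch: int = 8) -> np.ndarray:
    """Argmax labels for a (C, Z, H, W) standardised volume."""
    slices = np.moveaxis(data, 1, 0)  # (Z, C, H, W)
    out = []
    for start in range(0, slices.shape[0], batch):
        logits, _ = net.forward(slices[start:start + batch], train=False)
        out.append(np.argmax(logits, axis=1))
    return np.concatenate(out, axis=0)


def predict_mask(model: TrainedModel, volume: MESEVolume) -> LabelMask:
    """Per-slice argmax segmentation reassembled into a 3D label mask."""
    data = _volume_channels(volume, model.config.in_channels)
    net = UNet2D(model.config, params=model.params)
    labels = _predict_labels(net, data).astype(np.int16)
    label_dict = {name: i for i, name in enumerate(model.config.out_labels, start=1)}
    return LabelMask(labels, label_dict, volume.spacing_mm)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savez(d / "weights.npz", **model.params)
    cfg = asdict(model.config)
    cfg["out_labels"] = list(cfg["out_labels"])
    (d / "config.json").write_text(json.dumps(cfg, indent=1))
    (d / "history.json").write_text(json.dumps(
        {"history": model.history, "selected_epoch": model.selected_epoch}, indent=1))


def load_model(directory) -> TrainedModel:
    d = Path(directory)
    cfg = json.loads((d / "config.json").read_text())
    cfg["out_labels"] = tuple(cfg["out_labels"])
    config = UNetConfig(**cfg)
    with np.load(d / "weights.npz") as z:
        params = {k: z[k] for k in z.files}
    hist = json.loads((d / "history.json").read_text())
    return TrainedModel(params=params, config=config,
                        history=hist["history"], selected_epoch=hist["selected_epoch"])
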