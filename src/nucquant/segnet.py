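"""U-Net semantic segmentation: architecture, training loop, inference.

The default architecture is the classic encoder-decoder: four contraction
blocks of two 3x3 conv+ReLU layers each, 2x2 max-pooling between them, a
two-conv bottleneck, four expansion blocks with 2x2 stride-2 up-convolutions
and skip concatenation, and a final 1x1 projection to one foreground logit.
With the default configuration the layer walk counts 23 convolutional
layers (16 contraction/expansion 3x3 convs + 2 bottleneck convs + 4
up-convs + the 1x1 head); at depth ``d`` the census is ``5d + 3``.

The binary problem (background vs. biomarker-positive cell) is emitted as a
single sigmoid-activated logit, equivalent to a two-class softmax map.

The model runs on the numpy layer core in :mod:`nucquant.nn`; alternative
encoders can be registered via ``ENCODERS`` (the default, from-scratch
encoder is ``"classic-unet"``; pretrained backbones would plug in here).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .nn import (
    Adam,
    Conv2d,
    ConvTranspose2d,
    LossSpec,
    MaxPool2x2,
    ReLU,
    SGD,
    ReduceLROnPlateau,
    compute_loss,
)

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "UNet",
    "build_model",
    "count_conv_layers",
    "train",
    "predict",
    "save_model",
    "load_model",
    "soft_dice",
]


@dataclass(frozen=True)
class UNetConfig:
    input_size: tuple[int, int, int] = (256, 256, 3)
    depth: int = 4
    base_channels: int = 64
    encoder: str = "classic-unet"
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        h, w, c = self.input_size
        f = 2**self.depth
        if h % f or w % f:
            raise ValueError(
                f"input spatial dims {h}x{w} must be divisible by 2^depth={f}")
        if c != 3:
            raise ValueError("RGB input expected (3 channels)")
        if self.n_classes != 2:
            raise ValueError("binary segmentation only (2 classes)")
        if self.encoder not in ENCODERS:
            raise ValueError(f"unknown encoder {self.encoder!r}; "
                             f"available: {sorted(ENCODERS)}")


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"  # or "sgd" (Nesterov momentum)
    lr: float = 0.002
    momentum: float = 0.9
    weight_decay: float = 3e-5
    batch_size: int = 4
    epochs: int = 30
    lr_factor: float = 0.1
    lr_patience: int = 5
    monitor: str = "val_dice"  # or "train_loss"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer.lower() not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


class UNet:
    """Encoder-decoder with skip connections; explicit forward/backward."""

    def __init__(self, config: UNetConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        d, c = config.depth, config.base_channels
        self.enc_blocks = []
        in_ch = 3
        for k in range(d):
            ck = c * 2**k
            self.enc_blocks.append(
                [Conv2d(in_ch, ck, 3, rng), ReLU(), Conv2d(ck, ck, 3, rng), ReLU()]
            )
            in_ch = ck
        self.pools = [MaxPool2x2() for _ in range(d)]
        cb = c * 2**d
        self.bottleneck = [Conv2d(in_ch, cb, 3, rng), ReLU(),
                           Conv2d(cb, cb, 3, rng), ReLU()]
        self.ups = [ConvTranspose2d(cb, cb // 2, rng)]
        self.dec_blocks = []
        for k in range(d - 1, -1, -1):
            ck = c * 2**k
            block = [Conv2d(2 * ck, ck, 3, rng), ReLU(),
                     Conv2d(ck, ck, 3, rng), ReLU()]
            self.dec_blocks.append(block)
            if k > 0:
                self.ups.append(ConvTranspose2d(ck, ck // 2, rng))
        self.head = Conv2d(c, 1, 1, rng)

    @property
    def layers(self) -> list:
        out = []
        for block in self.enc_blocks:
            out.extend(block)
        out.extend(self.pools)
        out.extend(self.bottleneck)
        d = self.config.depth
        out.append(self.ups[0])
        for i, block in enumerate(self.dec_blocks):
            out.extend(block)
            if i < d - 1:
                out.append(self.ups[i + 1])
        out.append(self.head)
        return out

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """NCHW float32 in [0,1] -> foreground logits (N, 1, H, W)."""
        d = self.config.depth
        skips = []
        h = x
        for k in range(d):
            for layer in self.enc_blocks[k]:
                h = layer.forward(h)
            skips.append(h)
            h = self.pools[k].forward(h)
        for layer in self.bottleneck:
            h = layer.forward(h)
        h = self.ups[0].forward(h)
        self._skip_channels = []
        for i in range(d):
            skip = skips[d - 1 - i]
            self._skip_channels.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            for layer in self.dec_blocks[i]:
                h = layer.forward(h)
            if i < d - 1:
                h = self.ups[i + 1].forward(h)
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.config.depth
        g = self.head.backward(dlogits)
        dskips = [None] * d  # gradient flowing into each skip tensor
        for i in range(d - 1, -1, -1):
            if i < d - 1:
                g = self.ups[i + 1].backward(g)
            for layer in reversed(self.dec_blocks[i]):
                g = layer.backward(g)
            cs = self._skip_channels[i]
            dskips[d - 1 - i] = g[:, :cs]
            g = g[:, cs:]
        g = self.ups[0].backward(g)
        for layer in reversed(self.bottleneck):
            g = layer.backward(g)
        for k in range(d - 1, -1, -1):
            g = self.pools[k].backward(g)
            g = g + dskips[k]
            for layer in reversed(self.enc_blocks[k]):
                g = layer.backward(g)

    # -- parameter state ---------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            f"layer{i}.{name}": p
            for i, layer in enumerate(self.layers)
            for name, p in layer.params.items()
        }

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.array(state[f"layer{i}.{name}"],
                                              dtype=np.float32)


ENCODERS = {"classic-unet": UNet}


def build_model(config: UNetConfig | None = None, seed: int = 0) -> UNet:
    """Instantiate the network for ``config`` (defaults: the reference
    architecture with 23 convolutional layers)."""
    config = config or UNetConfig()
    return ENCODERS[config.encoder](config, seed=seed)


def count_conv_layers(model: UNet) -> int:
    """Layer walk counting convolutional layers (3x3 and 1x1 convolutions
    plus 2x2 up-convolutions)."""
    return sum(isinstance(l, (Conv2d, ConvTranspose2d)) for l in model.layers)


def _to_batch(images: Sequence[np.ndarray]) -> np.ndarray:
    arr = np.stack([np.asarray(im, dtype=np.float32) / 255.0 for im in images])
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def soft_dice(prob: np.ndarray, target: np.ndarray, eps: float = 1e-7) -> float:
    """Soft Dice coefficient between probabilities and a binary target."""
    prob = np.asarray(prob, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    inter = (prob * target).sum()
    return float((2 * inter + eps) / (prob.sum() + target.sum() + eps))


def _dataset_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    """Accepts IHCPatch sequences or (image, mask) tuples."""
    images, masks = [], []
    for item in dataset:
        if hasattr(item, "image"):
            images.append(item.image)
            masks.append(item.gt_binary)
        else:
            im, m = item
            images.append(im)
            masks.append(np.asarray(m) > 0)
    x = _to_batch(images)
    y = np.stack(masks).astype(np.float32)[:, None]
    return x, y


def train(
    model: UNet,
    train_set,
    train_val_set,
    cfg: TrainConfig,
    loss_spec: LossSpec | None = None,
):
    """Train ``model``; returns ``(model_at_best_validation, history)``.

    ``history`` is a list of per-epoch dicts
    ``{'epoch', 'train_loss', 'val_dice', 'lr'}``.  The learning rate
    follows reduce-on-plateau on the monitored metric (validation soft-Dice
    by default) and is therefore non-increasing; the parameters restored at
    the end are those of the best-validation epoch.
    """
    if len(train_set) == 0 or len(train_val_set) == 0:
        raise ValueError("train and train-val sets must be non-empty")
    loss_spec = loss_spec or LossSpec(("bce",))
    x_tr, y_tr = _dataset_arrays(train_set)
    x_va, y_va = _dataset_arrays(train_val_set)
    rng = np.random.default_rng(cfg.seed)
    if cfg.optimizer.lower() == "adam":
        opt = Adam(model.layers, lr=cfg.lr, weight_decay=cfg.weight_decay)
    else:
        opt = SGD(model.layers, lr=cfg.lr, momentum=cfg.momentum,
                  nesterov=True, weight_decay=cfg.weight_decay)
    mode = "max" if cfg.monitor == "val_dice" else "min"
    sched = ReduceLROnPlateau(opt, mode=mode, factor=cfg.lr_factor,
                              patience=cfg.lr_patience)
    n = x_tr.shape[0]
    history = []
    best_metric = -np.inf
    best_state = copy.deepcopy(model.state_dict())
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(x_tr[idx])
            loss, grad = compute_loss(logits, y_tr[idx], loss_spec,
                                      with_grad=True, from_logits=True)
            model.backward(grad.astype(np.float32))
            opt.step()
            losses.append(loss)
        val_probs = _sigmoid(model.forward(x_va))
        val_dice = soft_dice(val_probs, y_va)
        train_loss = float(np.mean(losses))
        monitored = val_dice if cfg.monitor == "val_dice" else train_loss
        lr_now = sched.step(monitored)
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_dice": val_dice, "lr": lr_now})
        score = monitored if mode == "max" else -monitored
        if score > best_metric:
            best_metric = score
            best_state = copy.deepcopy(model.state_dict())
    model.load_state_dict(best_state)
    return model, history


def predict(model: UNet, image: np.ndarray) -> np.ndarray:
    """Foreground probability map for one RGB image (H x W x 3, 8-bit).

    Spatial dims must be divisible by ``2**depth``; output shares H x W and
    lies in [0, 1].  Inference is deterministic.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    f = 2**model.config.depth
    h, w = image.shape[:2]
    if h % f or w % f:
        raise ValueError(f"spatial dims {h}x{w} not divisible by {f}")
    logits = model.forward(_to_batch([image]))
    return _sigmoid(logits)[0, 0].astype(np.float64)


def save_model(model: UNet, path) -> None:
    state = model.state_dict()
    meta = json.dumps({
        "input_size": model.config.input_size,
        "depth": model.config.depth,
        "base_channels": model.config.base_channels,
        "encoder": model.config.encoder,
        "n_classes": model.config.n_classes,
    })
    np.savez_compressed(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **state)


def load_model(path) -> UNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    cfg = UNetConfig(input_size=tuple(meta["input_size"]), depth=meta["depth"],
                     base_channels=meta["base_channels"], encoder=meta["encoder"],
                     n_classes=meta["n_classes"])
    model = build_model(cfg)
    model.load_state_dict(state)
    return model
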