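"""Size-parameterised SFCN binary sex classifier and its training protocol.

The SFCN (simple fully convolutional network) is a seven-block 3D CNN:
blocks 1-5 are 3x3x3 convolution + batch norm + 2x max pooling + ReLU,
block 6 is a 1x1x1 convolution + batch norm + ReLU, and block 7 is average
pooling over the remaining spatial extent, dropout (50% during training), and
a final 1x1x1 convolution to a single score. A sigmoid on that score gives
the probability of the positive class, here Male. The average-pool kernel is
derived from the input shape: five stride-2 floor halvings of each axis
(e.g. 193x229x193 -> 6x7x6).

Channel widths are configurable; the default is a narrow desk-scale stack
suitable for CPU training on 48^3 phantoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .errors import ConfigurationError, ShapeError
from .volume import Volume

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CHANNELS", "ModelSpec", "TrainConfig", "TrainedModel", "SFCN",
    "avgpool_kernel_for", "build_sfcn", "augment_rotate", "train",
]

DEFAULT_CHANNELS = (8, 16, 16, 32, 32, 16)


def avgpool_kernel_for(input_shape) -> tuple[int, int, int]:
    """Spatial extent left after five stride-2 floor halvings of each axis.

    This is the kernel of the head's average-pooling layer; each axis must
    survive the five halvings with at least one voxel.
    """
    kernel = []
    for axis, size in enumerate(input_shape):
        s = int(size)
        for _ in range(5):
            s //= 2
        if s < 1:
            raise ShapeError(
                f"input axis {axis} (size {input_shape[axis]}) collapses below "
                f"1 voxel after five stride-2 poolings; need >= 32")
        kernel.append(s)
    return tuple(kernel)


@dataclass(frozen=True)
class ModelSpec:
    input_shape: tuple[int, int, int]
    channels: tuple[int, ...]
    dropout_p: float = 0.5
    n_out: int = 1
    avgpool_kernel: tuple[int, int, int] = (1, 1, 1)


@dataclass
class TrainConfig:
    """Training protocol: Adam on binary cross-entropy, initial lr 0.01,
    batch 16, 50 epochs, lr x0.1 after 5 epochs without validation-loss
    improvement, and on-the-fly rotation augmentation (half the scans, up to
    15 degrees about a random axis)."""

    batch_size: int = 16
    lr0: float = 0.01
    epochs: int = 50
    plateau_factor: float = 0.1
    plateau_patience: int = 5
    aug_prob: float = 0.5
    aug_max_angle: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        errs = []
        if self.batch_size <= 0:
            errs.append("batch_size must be positive")
        if self.lr0 <= 0:
            errs.append("lr0 must be positive")
        if self.epochs <= 0:
            errs.append("epochs must be positive")
        if not 0.0 <= self.aug_prob <= 1.0:
            errs.append("aug_prob must be in [0, 1]")
        if not 0.0 < self.plateau_factor <= 1.0:
            errs.append("plateau_factor must be in (0, 1]")
        if errs:
            raise ConfigurationError(errs)


class SFCN:
    """The network plus its spec; wraps a :class:`brainsexmap.nn.Sequential`."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2 ** 31))
        ch = spec.channels
        layers = []
        prev = 1
        for c in ch[:5]:
            layers += [nn.Conv3d(prev, c, 3, rng=rng), nn.BatchNorm3d(c),
                       nn.MaxPool3d(), nn.ReLU()]
            prev = c
        layers += [nn.Conv3d(prev, ch[5], 1, rng=rng), nn.BatchNorm3d(ch[5]),
                   nn.ReLU()]
        layers += [nn.AvgPool3d(spec.avgpool_kernel),
                   nn.Dropout(spec.dropout_p, rng=self._dropout_rng),
                   nn.Conv3d(ch[5], spec.n_out, 1, rng=rng)]
        self.net = nn.Sequential(layers)

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.net.parameters())

    def _check_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None, None]
        elif x.ndim == 4:
            x = x[:, None]
        if x.shape[2:] != tuple(self.spec.input_shape):
            raise ShapeError(f"batch spatial shape {x.shape[2:]} does not "
                             f"match model input {self.spec.input_shape}")
        return x

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._check_batch(x)
        return self.net.forward(x, train=train).reshape(x.shape[0])

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Probability of Male for each volume in the batch (evaluation
        mode: dropout off, batch norm uses running statistics)."""
        return nn.sigmoid(self.logits(x, train=False))

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(pre-sigmoid score)/d(input voxel), one backward pass, eval mode."""
        x = self._check_batch(x)
        self.net.forward(x, train=False)
        g = self.net.backward(np.ones((x.shape[0], 1, 1, 1, 1), dtype=np.float32))
        return g[:, 0]


def build_sfcn(input_shape, channels=DEFAULT_CHANNELS, dropout_p: float = 0.5,
               seed: int = 0) -> SFCN:
    """Construct the classifier for a given input grid.

    The average-pool kernel is derived from ``input_shape`` by the
    floor-halving trace; the six ``channels`` are the conv-block widths.
    """
    channels = tuple(int(c) for c in channels)
    if len(channels) != 6:
        raise ConfigurationError(f"exactly 6 channel widths required, got {len(channels)}")
    spec = ModelSpec(input_shape=tuple(int(s) for s in input_shape),
                     channels=channels, dropout_p=dropout_p,
                     avgpool_kernel=avgpool_kernel_for(input_shape))
    return SFCN(spec, seed=seed)


def augment_rotate(vol: np.ndarray | Volume, prob: float = 0.5,
                   max_angle: float = 15.0,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """With probability ``prob``, rotate by an angle uniform in
    [-max_angle, +max_angle] degrees about a randomly chosen grid axis;
    otherwise return the input unchanged. Trilinear interpolation,
    background 0."""
    rng = rng or np.random.default_rng()
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    if rng.random() >= prob:
        return data
    axes_choices = ((0, 1), (0, 2), (1, 2))
    axes = axes_choices[rng.integers(3)]
    angle = rng.uniform(-max_angle, max_angle)
    return ndimage.rotate(data, angle, axes=axes, reshape=False, order=1,
                          mode="constant", cval=0.0).astype(np.float32)


@dataclass
class TrainedModel:
    model: SFCN
    history: list = field(default_factory=list)  # per-epoch dicts
    selected_epoch: int = -1                     # argmin of validation loss

    @property
    def val_losses(self) -> list[float]:
        return [h["val_loss"] for h in self.history]


def _epoch_val_loss(model: SFCN, x_val, y_val, batch_size) -> float:
    losses, counts = [], []
    for i in range(0, len(y_val), batch_size):
        z = model.logits(x_val[i:i + batch_size], train=False)
        loss, _ = nn.bce_with_logits(z, y_val[i:i + batch_size])
        losses.append(loss)
        counts.append(len(z))
    return float(np.average(losses, weights=counts))


def train(model: SFCN, train_set, val_set, cfg: TrainConfig) -> TrainedModel:
    """Run the training protocol and return the weights of the epoch with the
    lowest validation loss.

    ``train_set``/``val_set`` are ``(X, y)`` pairs with ``X`` of shape
    ``(n, D, H, W)`` and ``y`` binary (1 = Male). Deterministic for a fixed
    ``cfg.seed`` on a fixed BLAS configuration.
    """
    cfg.validate()
    x_tr, y_tr = train_set
    x_val, y_val = val_set
    x_tr = np.asarray(x_tr, dtype=np.float32)
    y_tr = np.asarray(y_tr, dtype=np.float32).ravel()
    x_val = np.asarray(x_val, dtype=np.float32)
    y_val = np.asarray(y_val, dtype=np.float32).ravel()
    if len(y_tr) == 0 or len(y_val) == 0:
        raise ConfigurationError("train and validation sets must be nonempty")
    if len(np.unique(y_tr)) < 2:
        raise ConfigurationError("training set contains a single class")

    rng = np.random.default_rng(cfg.seed)
    model._dropout_rng = np.random.default_rng(rng.integers(2 ** 31))
    for layer in model.net.layers:
        if isinstance(layer, nn.Dropout):
            layer.rng = model._dropout_rng
    first_conv = model.net.layers[0]
    first_conv.input_grad = False     # input gradients only matter for saliency
    opt = nn.Adam(model.net.parameters(), lr=cfg.lr0)
    sched = nn.ReduceLROnPlateau(opt, factor=cfg.plateau_factor,
                                 patience=cfg.plateau_patience)
    history = []
    best_state, best_val, best_epoch = None, np.inf, -1
    n = len(y_tr)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, counts = [], []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = np.stack([
                augment_rotate(x_tr[j], cfg.aug_prob, cfg.aug_max_angle, rng)
                if cfg.aug_prob > 0 else x_tr[j]
                for j in idx])
            yb = y_tr[idx]
            z = model.logits(xb, train=True)
            loss, dz = nn.bce_with_logits(z, yb)
            model.net.zero_grad()
            model.net.backward(dz.reshape(-1, 1, 1, 1, 1))
            opt.step()
            losses.append(loss)
            counts.append(len(idx))
        train_loss = float(np.average(losses, weights=counts))
        val_loss = _epoch_val_loss(model, x_val, y_val, cfg.batch_size)
        history.append({"epoch": epoch, "lr": float(opt.lr),
                        "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val:
            best_val, best_epoch = val_loss, epoch
            best_state = model.net.state_dict()
        sched.step(val_loss)
        log.info("epoch %02d lr=%.4g train=%.4f val=%.4f",
                 epoch, opt.lr, train_loss, val_loss)
    first_conv.input_grad = True
    model.net.load_state_dict(best_state)
    return TrainedModel(model=model, history=history, selected_epoch=best_epoch)
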