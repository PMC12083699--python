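"""U-Net surrogate of the Cellular-Potts transition map.

The network maps a 2-channel state (binary cell mask, normalized chemical
field) at MCS t to the state at t+100.  It is a standard encoder-decoder
with skip connections, built entirely from circular-padding convolutions so
the torus topology of the simulator is respected everywhere, with PReLU
activations.  Both output channels pass through a sigmoid: the cell channel
is a segmentation probability trained with binary cross-entropy, the field
channel a bounded regression trained with mean squared error weighted by 10.

Prediction binarizes the cell channel at a threshold (default 0.5); the
recursive rollout feeds the binarized mask and predicted field back as the
next input, so each iteration advances the represented time by 100 MCS.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .dataset import EncodedFrame
from .errors import ContractViolation, ParameterError, TrainingDivergedError

DEFAULT_THRESHOLD = 0.5


@dataclass
class SurrogateConfig:
    """Architecture and optimization hyper-parameters.

    The published description fixes the ingredients (U-Net, circular padding,
    PReLU, BCE + 10 x MSE loss, 100 epochs) but not depth, width, optimizer
    or learning rate; those defaults are package choices and config-exposed.
    """
    depth: int = 4
    base_channels: int = 64
    kernel_size: int = 3
    padding_mode: str = "periodic"
    activation: str = "prelu"
    batch_norm: bool = True
    loss_mse_weight: float = 10.0
    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    lattice_size: int = 256
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        if self.loss_mse_weight <= 0:
            raise ParameterError("loss_mse_weight must be > 0")
        if self.depth < 1 or self.base_channels < 1:
            raise ParameterError("depth and base_channels must be >= 1")
        if self.lattice_size % (1 << self.depth) != 0:
            raise ParameterError(
                f"lattice_size {self.lattice_size} must be divisible by "
                f"2^depth = {1 << self.depth}")
        if self.padding_mode != "periodic":
            raise ParameterError("only periodic padding is supported")


@dataclass
class PredictionFrame:
    """Surrogate output: cell probability, thresholded mask, bounded field."""
    cell_prob: np.ndarray
    cell_mask: np.ndarray
    field: np.ndarray
    mcs: int = -1

    def to_encoded(self) -> EncodedFrame:
        """Re-encode for feedback into the next surrogate step."""
        return EncodedFrame(cell=self.cell_mask.astype(np.uint8),
                            field=self.field.astype(np.float32), mcs=self.mcs)


class _ConvBlock:
    """(circular conv -> [BN] -> PReLU) x 2."""

    def __init__(self, c_in, c_out, k, rng, batch_norm):
        self.layers = []
        for ci in (c_in, c_out):
            self.layers.append(nn.Conv2dPeriodic(ci, c_out, k, rng))
            if batch_norm:
                self.layers.append(nn.BatchNorm2d(c_out))
            self.layers.append(nn.PReLU(c_out))

    def forward(self, x, train):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class UNet:
    """Encoder-decoder with skip connections, 2-in / 2-out channels."""

    def __init__(self, config: SurrogateConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, c, k = config.depth, config.base_channels, config.kernel_size
        bn = config.batch_norm
        self.enc = []
        ci = 2
        for i in range(d):
            self.enc.append(_ConvBlock(ci, c << i, k, rng, bn))
            ci = c << i
        self.pool = nn.AvgPool2()
        self.bottleneck = _ConvBlock(c << (d - 1), c << d, k, rng, bn)
        self.up = nn.BilinearUp2()
        self.dec = []
        for i in reversed(range(d)):
            self.dec.append(_ConvBlock((c << (i + 1)) + (c << i), c << i, k, rng, bn))
        self.head = nn.Conv2dPeriodic(c, 2, 1, rng)
        self._skip_channels = [c << i for i in range(d)]

    # -- plumbing ---------------------------------------------------------

    def _blocks(self):
        return self.enc + [self.bottleneck] + self.dec + [self.head]

    def layers(self):
        out = []
        for b in self._blocks():
            out.extend(b.layers if isinstance(b, _ConvBlock) else [b])
        return out

    def n_parameters(self) -> int:
        return sum(p.size for lay in self.layers() for p in lay.params.values())

    def state_dict(self) -> dict:
        state = {}
        for i, lay in enumerate(self.layers()):
            for k, v in lay.params.items():
                state[f"{i}.{k}"] = v.copy()
            if isinstance(lay, nn.BatchNorm2d):
                state[f"{i}.running_mean"] = lay.running_mean.copy()
                state[f"{i}.running_var"] = lay.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, lay in enumerate(self.layers()):
            for k in lay.params:
                lay.params[k][...] = state[f"{i}.{k}"]
            if isinstance(lay, nn.BatchNorm2d):
                lay.running_mean[...] = state[f"{i}.running_mean"]
                lay.running_var[...] = state[f"{i}.running_var"]

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits of shape (N, 2, H, W) for NCHW input (N, 2, H, W)."""
        if x.shape[-1] % (1 << self.config.depth) != 0 \
                or x.shape[-2] % (1 << self.config.depth) != 0:
            raise ContractViolation("input extent must be divisible by 2^depth")
        skips = []
        for block in self.enc:
            x = block.forward(x, train)
            skips.append(x)
            x = self.pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        for block, skip in zip(self.dec, reversed(skips)):
            x = self.up.forward(x, train)
            x = np.concatenate([x, skip], axis=1)
            x = block.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.config.depth
        dy = self.head.backward(dlogits)
        dskips = [None] * d
        # decoder blocks were applied deepest-first; mirror in reverse
        for j in range(d - 1, -1, -1):
            block = self.dec[j]
            dcat = block.backward(dy)
            cu = self.config.base_channels << (d - 1 - j + 1)
            dup, dskip = dcat[:, :cu], dcat[:, cu:]
            dskips[d - 1 - j] = dskip
            dy = self.up.backward(dup)
        dy = self.bottleneck.backward(dy)
        for i in range(d - 1, -1, -1):
            dy = self.pool.backward(dy)
            dy = dy + dskips[i]
            dy = self.enc[i].backward(dy)


def build_surrogate(config: SurrogateConfig) -> UNet:
    """Construct the U-Net; weight init is deterministic given config.seed."""
    return UNet(config)


def composite_loss(cell_prob: np.ndarray, field_pred: np.ndarray,
                   target: EncodedFrame, mse_weight: float = 10.0,
                   eps: float = 1e-7) -> float:
    """BCE(cell probability, cell target) + mse_weight * MSE(field)."""
    if cell_prob.shape != target.cell.shape or field_pred.shape != target.field.shape:
        raise ContractViolation("prediction and target shapes differ")
    p = np.clip(cell_prob.astype(np.float64), eps, 1.0 - eps)
    t = target.cell.astype(np.float64)
    bce = float(-np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))
    mse = float(np.mean((field_pred.astype(np.float64)
                         - target.field.astype(np.float64)) ** 2))
    return bce + mse_weight * mse


def _batch_arrays(pairs, idx):
    x = np.stack([pairs[i].input().stacked() for i in idx])
    t = np.stack([pairs[i].target().stacked() for i in idx])
    return x, t


def _loss_and_grad(logits, t, w):
    """Composite loss and its gradient w.r.t. the logits (both heads sigmoid)."""
    n = logits[:, 0].size
    p = nn.sigmoid(logits)
    p0, p1 = p[:, 0], p[:, 1]
    t0, t1 = t[:, 0], t[:, 1]
    z0 = logits[:, 0].astype(np.float64)
    # numerically stable BCE-with-logits: softplus(z) - t*z
    bce = float(np.mean(np.logaddexp(0.0, z0) - t0 * z0))
    mse = float(np.mean((p1 - t1) ** 2))
    dl = np.empty_like(logits)
    dl[:, 0] = (p0 - t0) / n
    dl[:, 1] = w * 2.0 * (p1 - t1) * p1 * (1.0 - p1) / n
    return bce + w * mse, dl


def evaluate_loss(model: UNet, pairs, batch_size: int = 16) -> float:
    """Mean composite loss over a pair set (eval mode)."""
    total, count = 0.0, 0
    for s in range(0, len(pairs), batch_size):
        idx = range(s, min(s + batch_size, len(pairs)))
        x, t = _batch_arrays(pairs, list(idx))
        logits = model.forward(x, train=False)
        loss, _ = _loss_and_grad(logits, t, model.config.loss_mse_weight)
        total += loss * len(x)
        count += len(x)
    return total / max(count, 1)


def train(model: UNet, train_pairs, test_pairs, config: SurrogateConfig):
    """Seeded Adam optimization of the composite loss.

    Returns (model, history); history holds per-epoch train/test loss, and
    the model ends up with the parameters of the best-test-loss epoch (final
    epoch when no test set is given).
    """
    if not train_pairs:
        raise ParameterError("train set must be nonempty")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.layers(), lr=config.learning_rate)
    history = {"train_loss": [], "test_loss": [], "best_epoch": None}
    best = (math.inf, None)
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_pairs))
        total, count = 0.0, 0
        for s in range(0, len(order), config.batch_size):
            idx = order[s:s + config.batch_size]
            x, t = _batch_arrays(train_pairs, idx)
            logits = model.forward(x, train=True)
            loss, dlogits = _loss_and_grad(logits, t, config.loss_mse_weight)
            if not math.isfinite(loss):
                raise TrainingDivergedError(epoch)
            model.backward(dlogits)
            opt.step()
            total += loss * len(x)
            count += len(x)
        history["train_loss"].append(total / count)
        if test_pairs:
            tl = evaluate_loss(model, test_pairs, config.batch_size)
            history["test_loss"].append(tl)
            if tl < best[0]:
                best = (tl, model.state_dict())
                history["best_epoch"] = epoch
        else:
            history["test_loss"].append(float("nan"))
    if best[1] is not None:
        model.load_state_dict(best[1])
    else:
        history["best_epoch"] = config.epochs - 1
    return model, history


def predict_step(model: UNet, frame: EncodedFrame,
                 threshold: float = DEFAULT_THRESHOLD) -> PredictionFrame:
    """One forward pass: 100 MCS ahead of ``frame``."""
    if frame.cell.shape != (model.config.lattice_size, model.config.lattice_size):
        raise ContractViolation(
            f"frame shape {frame.cell.shape} does not match the model's "
            f"lattice size {model.config.lattice_size}")
    x = frame.stacked()[None]
    logits = model.forward(x, train=False)
    p = nn.sigmoid(logits[0])
    cell_prob = p[0].astype(np.float64)
    field = np.clip(p[1], 0.0, 1.0).astype(np.float64)
    mcs = frame.mcs + 100 if frame.mcs >= 0 else -1
    return PredictionFrame(cell_prob=cell_prob,
                           cell_mask=(cell_prob >= threshold),
                           field=field, mcs=mcs)


def rollout(model: UNet, frame: EncodedFrame, n_iterations: int,
            threshold: float = DEFAULT_THRESHOLD) -> list[PredictionFrame]:
    """Recursive evaluation: feed each binarized prediction back as input.

    Frame i of the result represents MCS ``frame.mcs + 100 * (i + 1)``.
    """
    if n_iterations < 0:
        raise ParameterError("n_iterations must be >= 0")
    out = []
    current = frame
    for _ in range(n_iterations):
        pred = predict_step(model, current, threshold)
        out.append(pred)
        current = pred.to_encoded()
    return out


def save_model(path, model: UNet, manifest_hash: str = "") -> None:
    state = model.state_dict()
    np.savez_compressed(path, __config__=json.dumps(asdict(model.config)),
                        __manifest_hash__=manifest_hash, **state)


def load_model(path) -> UNet:
    with np.load(path, allow_pickle=False) as data:
        config = SurrogateConfig(**json.loads(str(data["__config__"])))
        model = build_surrogate(config)
        state = {k: data[k] for k in data.files if not k.startswith("__")}
        model.load_state_dict(state)
    return model
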