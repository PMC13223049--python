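"""Custom forward/reverse CNN families and their training loop.

Two families of VGG-style convolutional classifiers are defined by their
per-block channel schedule:

* **forward** — channels widen with depth (64 -> 128 -> 256 -> 512), the
  classical pattern;
* **reverse** — channels narrow with depth (512 -> 256 -> 128 -> 64). With a
  2x2 max pool per block this is a "double compression": channel depth and
  spatial resolution shrink together, an aggressive information bottleneck
  that discards speckle-like high-frequency texture while keeping the
  anatomy that discriminates sex.

Each block is ``convs_per_block`` 3x3/stride-1/pad-1 convolutions with ReLU
followed by one 2x2 max pool; a single dropout stage sits at the end of the
convolutional stack, immediately before flattening, ahead of the dense head
and a single sigmoid output trained with binary cross-entropy. Size variants
S/M/L use 2/3/4 blocks, taking channel counts from the start of the family's
schedule.

The net is implemented directly on numpy (im2col convolutions, explicit
backprop) with SGD-with-momentum and Adam optimizers; training is fully
seeded, records per-epoch train/val loss and accuracy, checkpoints the best
validation loss below a quality gate, and early-stops on patience after a
monitoring warm-up.
"""

from __future__ import annotations

import copy
import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seeds import rng_for

REVERSE_SCHEDULE = (512, 256, 128, 64)
FORWARD_SCHEDULE = (64, 128, 256, 512)
VARIANT_BLOCKS = {"S": 2, "M": 3, "L": 4}


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CNNConfig:
    """Architecture description for one custom CNN."""

    family: str = "reverse"  # "forward" | "reverse"
    size_variant: str = "L"  # S/M/L -> 2/3/4 blocks
    schedule: tuple[int, ...] | None = None  # explicit per-block channels (overrides variant)
    convs_per_block: int = 2
    input_size: int = 64
    dropout_rate: float = 0.3
    dense_head: tuple[int, ...] = (64,)

    def resolved_schedule(self) -> tuple[int, ...]:
        if self.schedule is not None:
            sched = tuple(int(c) for c in self.schedule)
        else:
            if self.size_variant not in VARIANT_BLOCKS:
                raise ValueError(f"size_variant must be one of {sorted(VARIANT_BLOCKS)}")
            base = REVERSE_SCHEDULE if self.family == "reverse" else FORWARD_SCHEDULE
            sched = base[: VARIANT_BLOCKS[self.size_variant]]
        if self.family == "reverse":
            if not all(a > b for a, b in zip(sched, sched[1:])):
                raise ValueError(f"reverse family requires strictly decreasing channels, got {sched}")
        elif self.family == "forward":
            if not all(a < b for a, b in zip(sched, sched[1:])):
                raise ValueError(f"forward family requires strictly increasing channels, got {sched}")
        else:
            raise ValueError(f"family must be 'forward' or 'reverse', got {self.family!r}")
        return sched

    @property
    def n_blocks(self) -> int:
        return len(self.resolved_schedule())

    def validate(self) -> None:
        sched = self.resolved_schedule()
        if self.input_size % (2 ** len(sched)) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{len(sched)} (one pool per block)"
            )
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.convs_per_block < 1:
            raise ValueError("convs_per_block must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Training-loop hyperparameters (defaults suit full-scale training runs;
    see ``desk_scale_train_config`` for the small-problem preset)."""

    batch_size: int = 16
    optimizer: str = "adam"  # "adam" | "sgd"
    learning_rate: float = 1e-3
    momentum: float = 0.9
    max_epochs: int = 300
    monitor_start_epoch: int = 100
    patience: int = 500
    checkpoint_gate: float = 0.70
    seed: int = 0
    warm_start: dict | None = None  # a state dict from a previous run

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.monitor_start_epoch < 0:
            raise ValueError("monitor_start_epoch must be >= 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


def desk_scale_train_config(**overrides) -> TrainConfig:
    """Small-problem preset: monitor from the start, short patience."""
    base = dict(max_epochs=60, monitor_start_epoch=0, patience=30)
    base.update(overrides)
    return TrainConfig(**base)


# ---------------------------------------------------------------------------
# layers


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C*9, H*W) patches for a 3x3/stride-1/pad-1 conv."""
    N, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((N, C, 9, H, W), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[:, :, k] = xp[:, :, di : di + H, dj : dj + W]
            k += 1
    return cols.reshape(N, C * 9, H * W)


def _col2im3(dcols: np.ndarray, shape: tuple) -> np.ndarray:
    N, C, H, W = shape
    d = dcols.reshape(N, C, 9, H, W)
    dxp = np.zeros((N, C, H + 2, W + 2), dtype=dcols.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di : di + H, dj : dj + W] += d[:, :, k]
            k += 1
    return dxp[:, :, 1:-1, 1:-1]


class Conv3x3:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / (cin * 9))  # He init for ReLU stacks
        self.params = {
            "W": rng.normal(0.0, scale, size=(cout, cin * 9)).astype(np.float32),
            "b": np.zeros(cout, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.cin, self.cout = cin, cout

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        self._cols = _im2col3(x)
        N, _, H, W = x.shape
        out = np.einsum("of,nfp->nop", self.params["W"], self._cols, optimize=True)
        out += self.params["b"][None, :, None]
        return out.reshape(N, self.cout, H, W)

    def backward(self, dout):
        N, _, H, W = self._shape
        d2 = dout.reshape(N, self.cout, H * W)
        self.grads["W"][:] = np.einsum("nop,nfp->of", d2, self._cols, optimize=True)
        self.grads["b"][:] = d2.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", self.params["W"], d2, optimize=True)
        return _col2im3(dcols, self._shape)


class ReLU:
    params: dict = {}
    grads: dict = {}

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2:
    params: dict = {}
    grads: dict = {}

    def forward(self, x, train=False, rng=None):
        N, C, H, W = x.shape
        x6 = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
        idx = x6.argmax(axis=-1)
        self._idx, self._shape = idx, x.shape
        return np.take_along_axis(x6, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        N, C, H, W = self._shape
        d6 = np.zeros((N, C, H // 2, W // 2, 4), dtype=dout.dtype)
        np.put_along_axis(d6, self._idx[..., None], dout[..., None], axis=-1)
        return d6.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)


class Dropout:
    params: dict = {}
    grads: dict = {}

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten:
    params: dict = {}
    grads: dict = {}

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / nin)
        self.params = {
            "W": rng.normal(0.0, scale, size=(nin, nout)).astype(np.float32),
            "b": np.zeros(nout, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"][:] = self._x.T @ dout
        self.grads["b"][:] = dout.sum(axis=0)
        return dout @ self.params["W"].T


# ---------------------------------------------------------------------------
# model


class CNNModel:
    """An executable custom CNN with introspectable structure."""

    def __init__(self, config: CNNConfig, seed: int = 0):
        config.validate()
        self.config = config
        sched = config.resolved_schedule()
        rng = rng_for(seed, "init", config.family, config.size_variant, *sched)
        layers: list = []
        self.block_channels = list(sched)
        cin = 1
        for cout in sched:
            for _ in range(config.convs_per_block):
                layers.append(Conv3x3(cin, cout, rng))
                layers.append(ReLU())
                cin = cout
            layers.append(MaxPool2())
        layers.append(Dropout(config.dropout_rate))
        layers.append(Flatten())
        spatial = config.input_size // (2 ** len(sched))
        nin = sched[-1] * spatial * spatial
        for width in config.dense_head:
            layers.append(Dense(nin, width, rng))
            layers.append(ReLU())
            nin = width
        layers.append(Dense(nin, 1, rng))
        self.layers = layers
        self.pre_flatten_spatial = (spatial, spatial)

    # -- introspection -----------------------------------------------------
    @property
    def dropout_indices(self) -> list[int]:
        return [i for i, l in enumerate(self.layers) if isinstance(l, Dropout)]

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for l in self.layers for v in l.params.values()))

    # -- execution ---------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False, rng=None, collect: bool = False):
        """Logits for a (N, 1, H, W) float batch; with ``collect`` also the
        list of every layer's output (for activation maps)."""
        acts = []
        out = x
        for layer in self.layers:
            out = layer.forward(out, train=train, rng=rng)
            if collect:
                acts.append(out)
        logits = out[:, 0]
        return (logits, acts) if collect else logits

    def backward(self, dlogits: np.ndarray) -> None:
        dout = dlogits[:, None].astype(np.float32)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def scores(self, x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.forward(x)))

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict:
        return {
            i: {k: v.copy() for k, v in l.params.items()}
            for i, l in enumerate(self.layers)
            if l.params
        }

    def load_state_dict(self, state: dict) -> None:
        for i, params in state.items():
            for k, v in params.items():
                if self.layers[int(i)].params[k].shape != v.shape:
                    raise ValueError("checkpoint architecture does not match this model")
                self.layers[int(i)].params[k][:] = v

    def zero_all_weights(self) -> None:
        for l in self.layers:
            for v in l.params.values():
                v[:] = 0


def build_cnn(config: CNNConfig, seed: int = 0) -> CNNModel:
    """Construct and initialize a model from its configuration."""
    return CNNModel(config, seed=seed)


# ---------------------------------------------------------------------------
# optimizers


class _SGD:
    def __init__(self, model, lr, momentum):
        self.lr, self.momentum = lr, momentum
        self.v = [{k: np.zeros_like(p) for k, p in l.params.items()} for l in model.layers]

    def step(self, model):
        for l, v in zip(model.layers, self.v):
            for k, p in l.params.items():
                v[k] = self.momentum * v[k] - self.lr * l.grads[k]
                p += v[k]


class _Adam:
    def __init__(self, model, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(p) for k, p in l.params.items()} for l in model.layers]
        self.v = [{k: np.zeros_like(p) for k, p in l.params.items()} for l in model.layers]

    def step(self, model):
        self.t += 1
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for l, m, v in zip(model.layers, self.m, self.v):
            for k, p in l.params.items():
                g = l.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / c1) / (np.sqrt(v[k] / c2) + self.eps)


# ---------------------------------------------------------------------------
# training


def _as_batch(frames: np.ndarray) -> np.ndarray:
    x = np.asarray(frames, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None]
    if x.max() > 1.5:  # 8-bit inputs -> [0, 1]
        x = x / 255.0
    return x


def _encode_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        bad = set(np.unique(arr)) - {"F", "M"}
        if bad:
            raise ValueError(f"non-binary labels: {bad}")
        return (arr == "M").astype(np.float32)
    u = set(np.unique(arr))
    if not u <= {0, 1}:
        raise ValueError(f"non-binary labels: {u}")
    return arr.astype(np.float32)


def bce_loss_and_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy on logits; grad wrt logits."""
    z = logits.astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = 1.0 / (1.0 + np.exp(-z))
    return loss, ((p - y) / len(y)).astype(np.float32)


def evaluate_loss(model: CNNModel, X: np.ndarray, y: np.ndarray, batch: int = 64) -> tuple[float, float]:
    losses, hits, n = 0.0, 0, len(y)
    for i in range(0, n, batch):
        z = model.forward(X[i : i + batch])
        l, _ = bce_loss_and_grad(z, y[i : i + batch])
        losses += l * len(z)
        hits += int(((z >= 0) == (y[i : i + batch] >= 0.5)).sum())
    return losses / n, hits / n


@dataclass
class TrainingHistory:
    """Per-epoch curves plus the epochs at which checkpoint/stop fired."""

    table: pd.DataFrame
    best_epoch: int | None
    stopped_epoch: int


def train_model(
    model: CNNModel,
    train_frames,
    train_labels,
    val_frames,
    val_labels,
    train_cfg: TrainConfig | None = None,
    augment=None,
) -> tuple[TrainingHistory, dict | None]:
    """Train with BCE on a single sigmoid output.

    ``augment(image_u8, seed) -> image_u8`` is applied per sample per epoch
    (train-time augmentation). The best checkpoint is the lowest validation
    loss among epochs where it is below ``checkpoint_gate``; early stopping
    triggers after ``patience`` epochs without validation-loss improvement,
    with monitoring active from ``monitor_start_epoch``. The model is left
    loaded with the best checkpoint when one exists.
    """
    cfg = train_cfg or TrainConfig()
    if len(np.asarray(train_frames)) == 0 or len(np.asarray(val_frames)) == 0:
        raise ValueError("empty train or validation partition")
    y_tr = _encode_labels(train_labels)
    y_va = _encode_labels(val_labels)
    raw_train = np.asarray(train_frames)
    X_tr = _as_batch(raw_train)
    X_va = _as_batch(np.asarray(val_frames))
    if cfg.warm_start is not None:
        model.load_state_dict(cfg.warm_start)
    opt = (
        _Adam(model, cfg.learning_rate)
        if cfg.optimizer == "adam"
        else _SGD(model, cfg.learning_rate, cfg.momentum)
    )
    rng = rng_for(cfg.seed, "train-loop")
    drop_rng = rng_for(cfg.seed, "dropout")

    rows = []
    best_val = math.inf
    best_state = None
    best_epoch = None
    monitor_best = math.inf
    since_improve = 0
    stopped = cfg.max_epochs
    n = len(y_tr)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        ep_loss, ep_hits = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            if augment is not None:
                xb = _as_batch(
                    np.stack([augment(raw_train[j], seed=int(rng.integers(2**31 - 1))) for j in idx])
                )
            else:
                xb = X_tr[idx]
            yb = y_tr[idx]
            z = model.forward(xb, train=True, rng=drop_rng)
            loss, dz = bce_loss_and_grad(z, yb)
            model.backward(dz)
            opt.step(model)
            ep_loss += loss * len(idx)
            ep_hits += int(((z >= 0) == (yb >= 0.5)).sum())
        val_loss, val_acc = evaluate_loss(model, X_va, y_va)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": ep_loss / n,
                "train_acc": ep_hits / n,
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_loss < cfg.checkpoint_gate and val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
        if epoch >= cfg.monitor_start_epoch:
            if val_loss < monitor_best - 1e-12:
                monitor_best = val_loss
                since_improve = 0
            else:
                since_improve += 1
            if since_improve >= cfg.patience:
                stopped = epoch
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    history = TrainingHistory(pd.DataFrame(rows), best_epoch, stopped)
    return history, best_state


def predict(model: CNNModel, frames, threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Labels + sigmoid scores for a batch of frames. Label is M iff score >= threshold."""
    X = _as_batch(np.asarray(frames))
    if X.shape[-1] != model.config.input_size or X.shape[-2] != model.config.input_size:
        raise ValueError(
            f"frame size {X.shape[-2:]} incompatible with model input {model.config.input_size}"
        )
    scores = np.concatenate([model.scores(X[i : i + 64]) for i in range(0, len(X), 64)])
    labels = np.where(scores >= threshold, "M", "F")
    return labels, scores


# ---------------------------------------------------------------------------
# grid bookkeeping


@dataclass(frozen=True)
class HyperparameterGrid:
    """Structures x per-structure training combinations."""

    structures: tuple[CNNConfig, ...]
    learning_rates: tuple[float, ...]
    dropout_rates: tuple[float, ...]
    optimizers: tuple[str, ...] = ("sgd", "adam")

    @property
    def n_combinations(self) -> int:
        return len(self.learning_rates) * len(self.dropout_rates) * len(self.optimizers)

    @property
    def n_total(self) -> int:
        return len(self.structures) * self.n_combinations


def enumerate_grid(grid: HyperparameterGrid) -> list[tuple[CNNConfig, TrainConfig]]:
    """Deterministic Cartesian expansion of the grid into trainable specs."""
    if not grid.structures or grid.n_combinations == 0:
        raise ValueError("empty grid")
    out = []
    for structure in grid.structures:
        for lr, dr, opt in itertools.product(grid.learning_rates, grid.dropout_rates, grid.optimizers):
            out.append(
                (replace(structure, dropout_rate=dr), TrainConfig(learning_rate=lr, optimizer=opt))
            )
    return out


def full_scale_grid() -> HyperparameterGrid:
    """The full-scale tuning grid: 22 structures x 44 combinations = 968 specs.

    The structure set is a repo convention (family x size variant crossed
    with head width and per-block conv depth); the combination axes are 11
    learning rates x 2 dropout rates x 2 optimizers.
    """
    structures: list[CNNConfig] = []
    for family in ("forward", "reverse"):
        for variant in ("S", "M", "L"):
            for head in ((64,), (128,)):
                structures.append(CNNConfig(family=family, size_variant=variant, dense_head=head))
            structures.append(CNNConfig(family=family, size_variant=variant, convs_per_block=1))
        for variant in ("M", "L"):
            structures.append(CNNConfig(family=family, size_variant=variant, convs_per_block=3))
    lrs = (1e-2, 5e-3, 2e-3, 1e-3, 5e-4, 2e-4, 1e-4, 5e-5, 2e-5, 1e-5, 5e-6)
    return HyperparameterGrid(tuple(structures), lrs, (0.3, 0.5), ("sgd", "adam"))
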