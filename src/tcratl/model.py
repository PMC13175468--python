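"""Trunk + head models, Poisson-loss training, and the four fine-tuning levels.

The trunk follows the standard sequence-to-profile layout — a strided
convolution stem that pools 1-bp resolution down to 128-bp bins, a stack of
self-attention (transformer) blocks, and a pointwise convolution — and ends
in a replaceable output head (linear map to k tracks + softplus). Transfer
learning replaces the head and re-trains a level-dependent subset of
parameters:

    level 1: head only
    level 2: head + pointwise convolution
    level 3: + the last transformer block
    level 4: + the last 11 transformer blocks (all of them when fewer exist)

Training minimizes the Poisson negative log-likelihood
``mean(pred - target * log(pred))`` with Adam (default lr 1e-4, batch 64)
and stops early once the validation-loss improvement stays below 0.001 for
five consecutive evaluations; the checkpoint with minimal validation loss is
returned. A from-scratch CNN baseline (kernel 15, strides 2/4/4/4) shares
the training loop for like-for-like comparisons.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from typing import Callable

import numpy as np

from ._nn import (
    Adam,
    Conv1d,
    LayerNorm,
    Linear,
    Module,
    ReLU,
    Sequential,
    Softplus,
    TransformerBlock,
)
from .data_prep import DatasetSplit, PrepConfig

_STEM_STRIDES = (2, 4, 4, 4)  # product 128 = one output bin per 128 bp


class SurrogateTrunk(Module):
    """Small sequence-to-profile trunk: conv stem -> transformers -> pointwise.

    Maps (B, L, 4) one-hot input to a (B, n_bins, C) embedding at 128-bp
    resolution, cropping ``cfg.crop`` bp worth of bins from each end. Blocks
    are individually freezable by name (``conv_stack``, ``transformer_stack.i``,
    ``pointwise_conv``).
    """

    def __init__(self, cfg: PrepConfig, C: int = 64, n_blocks: int = 2, seed: int = 0,
                 stem_channels: tuple[int, ...] = (64, 64, 64)):
        super().__init__()
        if cfg.bin_size != int(np.prod(_STEM_STRIDES)):
            raise ValueError("trunk pools by 128; PrepConfig.bin_size must be 128")
        if cfg.crop % cfg.bin_size != 0:
            raise ValueError("crop must be a whole number of bins")
        rng = np.random.default_rng(seed)
        self.cfg, self.C, self.n_blocks = cfg, C, n_blocks
        self.crop_bins = cfg.crop // cfg.bin_size
        chans = (4,) + tuple(stem_channels) + (C,)
        stem = []
        for i, stride in enumerate(_STEM_STRIDES):
            stem += [Conv1d(chans[i], chans[i + 1], kernel=15 if i == 0 else 5,
                            stride=stride, rng=rng), ReLU()]
        self.conv_stack = self.add_module("conv_stack", Sequential(*stem))
        self.transformer_stack = self.add_module(
            "transformer_stack", Sequential(*[TransformerBlock(C, rng) for _ in range(n_blocks)])
        )
        self.pointwise_conv = self.add_module(
            "pointwise_conv", Sequential(Linear(C, C, rng), ReLU(), LayerNorm(C))
        )

    def forward(self, x, train=False):
        if x.shape[1] != self.cfg.L:
            raise ValueError(f"input length {x.shape[1]} != configured L {self.cfg.L}")
        h = self.conv_stack(x, train=train)
        h = self.transformer_stack(h, train=train)
        h = self.pointwise_conv(h, train=train)
        c = self.crop_bins
        self._pre_crop_bins = h.shape[1]
        return h[:, c : h.shape[1] - c]

    def backward(self, dy):
        c = self.crop_bins
        dh = np.zeros((dy.shape[0], self._pre_crop_bins, dy.shape[2]), dtype=dy.dtype)
        dh[:, c : self._pre_crop_bins - c] = dy
        dh = self.pointwise_conv.backward(dh)
        dh = self.transformer_stack.backward(dh)
        return self.conv_stack.backward(dh)


class HeadModel(Module):
    """Linear (C -> k) + softplus output head; strictly positive outputs."""

    def __init__(self, C: int, k: int, seed: int = 0):
        super().__init__()
        if k <= 0:
            raise ValueError("k must be positive")
        rng = np.random.default_rng(seed)
        self.C, self.k = C, k
        self.linear = self.add_module("linear", Linear(C, k, rng))
        self.act = self.add_module("act", Softplus())

    def forward(self, x, train=False):
        return self.act(self.linear(x, train=train), train=train)

    def backward(self, dy):
        return self.linear.backward(self.act.backward(dy))


class _ProfileModel(Module):
    """Shared inference helpers for trunk+head and CNN models."""

    k: int
    cfg: PrepConfig

    def predict(self, one_hot: np.ndarray) -> np.ndarray:
        """(L, 4) -> (n_bins, k), deterministic."""
        return self.forward(one_hot[None], train=False)[0]

    def predict_batch(self, one_hot: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """(B, L, 4) -> (B, n_bins, k)."""
        outs = [
            self.forward(one_hot[i : i + batch_size], train=False)
            for i in range(0, one_hot.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)


class TLModel(_ProfileModel):
    """Pluggable trunk + replaceable head."""

    def __init__(self, trunk: SurrogateTrunk, head: HeadModel):
        super().__init__()
        if head.C != trunk.C:
            raise ValueError("head width does not match trunk channels")
        self.trunk = self.add_module("trunk", trunk)
        self.head = self.add_module("head", head)
        self.cfg = trunk.cfg
        self.k = head.k

    def forward(self, x, train=False):
        return self.head(self.trunk(x, train=train), train=train)

    def backward(self, dy):
        return self.trunk.backward(self.head.backward(dy))

    def trainable_names(self, level: int) -> set[str]:
        """Parameter names trained at a given fine-tuning level."""
        if level not in (1, 2, 3, 4):
            raise ValueError(f"fine-tuning level must be 1-4, got {level}")
        prefixes = ["head."]
        if level >= 2:
            prefixes.append("trunk.pointwise_conv.")
        B = self.trunk.n_blocks
        if level == 3:
            prefixes.append(f"trunk.transformer_stack.{B - 1}.")
        elif level == 4:
            for i in range(max(0, B - 11), B):
                prefixes.append(f"trunk.transformer_stack.{i}.")
        return {
            n for n in self.named_parameters() if any(n.startswith(p) for p in prefixes)
        }


def replace_head(trunk: SurrogateTrunk, k: int, seed: int = 0) -> TLModel:
    """Head replacement: copy the (pretrained) trunk, attach a fresh head."""
    return TLModel(copy.deepcopy(trunk), HeadModel(trunk.C, k, seed=seed))


class BaselineCNN(_ProfileModel):
    """From-scratch CNN: symmetric bp crop, then four strided convs + head.

    Kernel size 15 with strides 2, 4, 4, 4 (full-scale channels
    128/256/512/512; desk-scale presets shrink channels, never the
    stride/crop geometry).
    """

    def __init__(self, k: int, cfg: PrepConfig,
                 channels: tuple[int, int, int, int] = (128, 256, 512, 512),
                 seed: int = 0):
        super().__init__()
        retained = cfg.L - 2 * cfg.crop
        if retained % int(np.prod(_STEM_STRIDES)) != 0:
            raise ValueError("retained length not divisible by total stride 128")
        rng = np.random.default_rng(seed)
        self.cfg, self.k = cfg, k
        self.crop_bp = cfg.crop
        chans = (4,) + tuple(channels)
        layers = []
        for i, stride in enumerate(_STEM_STRIDES):
            layers += [Conv1d(chans[i], chans[i + 1], kernel=15, stride=stride, rng=rng), ReLU()]
        self.conv = self.add_module("conv", Sequential(*layers))
        self.proj = self.add_module("proj", Linear(channels[-1], k, rng))
        self.act = self.add_module("act", Softplus())

    @property
    def n_bins(self) -> int:
        return (self.cfg.L - 2 * self.cfg.crop) // int(np.prod(_STEM_STRIDES))

    def forward(self, x, train=False):
        if x.shape[1] != self.cfg.L:
            raise ValueError(f"input length {x.shape[1]} != configured L {self.cfg.L}")
        xc = x[:, self.crop_bp : x.shape[1] - self.crop_bp]
        h = self.conv(xc, train=train)
        return self.act(self.proj(h, train=train), train=train)

    def backward(self, dy):
        dh = self.proj.backward(self.act.backward(dy))
        dxc = self.conv.backward(dh)
        B, _, _ = dxc.shape
        dx = np.zeros((B, self.cfg.L, 4), dtype=dxc.dtype)
        dx[:, self.crop_bp : self.cfg.L - self.crop_bp] = dxc
        return dx

    def trainable_names(self, level: int | None = None) -> set[str]:
        # trained de novo: every parameter, regardless of requested level
        return set(self.named_parameters())


def build_baseline_cnn(k: int, cfg: PrepConfig,
                       channels: tuple[int, int, int, int] = (128, 256, 512, 512),
                       seed: int = 0) -> BaselineCNN:
    return BaselineCNN(k, cfg, channels=channels, seed=seed)


# ------------------------------------------------------------------ loss


def poisson_nll(pred: np.ndarray, target: np.ndarray) -> float:
    """mean(pred - target * log(pred)); no log-factorial term.

    The omitted ``log(target!)`` constant does not depend on the prediction
    and is irrelevant to optimization. Predictions must be strictly positive
    (the softplus output guarantees it).
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    if (pred <= 0).any():
        raise ValueError("predictions must be strictly positive")
    if (target < 0).any():
        raise ValueError("targets must be nonnegative")
    return float(np.mean(pred - target * np.log(pred)))


def poisson_nll_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """d/dpred of the mean Poisson NLL."""
    return (1.0 - target / pred) / pred.size


# ------------------------------------------------------------------ training


@dataclasses.dataclass
class FineTuneConfig:
    level: int
    learning_rate: float = 1e-4
    batch_size: int = 64
    early_stop_delta: float = 1e-3
    early_stop_patience: int = 5
    max_steps: int = 1000
    eval_interval: int | None = None  # default: one evaluation per epoch

    def __post_init__(self):
        if self.level not in (1, 2, 3, 4):
            raise ValueError(f"fine-tuning level must be 1-4, got {self.level}")

    @classmethod
    def desk(cls, level: int, **kw) -> "FineTuneConfig":
        """Desk-scale training preset (small surrogate, short step budgets)."""
        args = dict(level=level, learning_rate=5e-3, batch_size=16, max_steps=300,
                    eval_interval=25)
        args.update(kw)
        return cls(**args)


@dataclasses.dataclass
class TrainingHistory:
    steps: list[int]
    train_losses: list[float]
    valid_losses: list[float]
    stop_reason: str
    best_index: int

    @property
    def best_valid_loss(self) -> float:
        return self.valid_losses[self.best_index]


def _dataset_arrays(ds: DatasetSplit) -> tuple[np.ndarray, np.ndarray]:
    from ._nn import DEFAULT_DTYPE

    if len(ds) == 0:
        raise ValueError(f"{ds.label} dataset is empty")
    return ds.inputs().astype(DEFAULT_DTYPE), ds.targets().astype(DEFAULT_DTYPE)


def _eval_loss(model: Module, X: np.ndarray, Y: np.ndarray, batch: int = 32) -> float:
    total, count = 0.0, 0
    for i in range(0, X.shape[0], batch):
        pred = model.forward(X[i : i + batch], train=False)
        t = Y[i : i + batch]
        total += float(np.sum(pred - t * np.log(pred)))
        count += t.size
    return total / count


def _train_loop(
    model: Module,
    trainable: set[str],
    Xtr: np.ndarray,
    Ytr: np.ndarray,
    Xva: np.ndarray,
    Yva: np.ndarray,
    lr: float,
    batch_size: int,
    max_steps: int,
    delta: float,
    patience: int,
    eval_interval: int,
    seed: int,
    valid_loss_fn: Callable[[Module], float] | None = None,
) -> TrainingHistory:
    rng = np.random.default_rng(seed)
    opt = Adam(model, trainable, lr=lr)
    n = Xtr.shape[0]
    order = rng.permutation(n)
    cursor = 0

    def valid_loss() -> float:
        if valid_loss_fn is not None:
            return float(valid_loss_fn(model))
        return _eval_loss(model, Xva, Yva)

    steps, tr_losses, va_losses = [], [], []
    best_idx, best_loss, best_state = -1, math.inf, None
    prev_loss, streak = None, 0
    stop_reason = "max_steps"
    last_train = math.nan

    for step in range(1, max_steps + 1):
        if cursor + batch_size > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor : cursor + batch_size]
        cursor += batch_size
        xb, yb = Xtr[idx], Ytr[idx]
        pred = model.forward(xb, train=True)
        last_train = poisson_nll(pred, yb)
        model.zero_grad()
        model.backward(poisson_nll_grad(pred, yb))
        opt.step()

        if step % eval_interval == 0 or step == max_steps:
            vl = valid_loss()
            steps.append(step)
            tr_losses.append(last_train)
            va_losses.append(vl)
            if vl < best_loss:
                best_loss = vl
                best_idx = len(va_losses) - 1
                params = model.named_parameters()
                best_state = {name: params[name].copy() for name in trainable}
            if prev_loss is not None:
                streak = streak + 1 if (prev_loss - vl) < delta else 0
            prev_loss = vl
            if streak >= patience:
                stop_reason = "early_stop"
                break

    if best_state is not None:
        params = model.named_parameters()
        for name, value in best_state.items():
            params[name][...] = value
    return TrainingHistory(steps, tr_losses, va_losses, stop_reason, best_idx)


def fine_tune(
    model,
    train_ds: DatasetSplit,
    valid_ds: DatasetSplit,
    cfg: FineTuneConfig,
    seed: int = 0,
    valid_loss_fn: Callable[[Module], float] | None = None,
):
    """Train the level-designated parameter subset; frozen parameters are
    bit-identical before and after (the optimizer never touches them).

    Validation is evaluated every ``eval_interval`` steps (default: once per
    epoch); training stops early after ``early_stop_patience`` consecutive
    evaluations whose improvement is below ``early_stop_delta``, and the
    best-validation checkpoint is restored. Returns (model, TrainingHistory).
    """
    Xtr, Ytr = _dataset_arrays(train_ds)
    Xva, Yva = _dataset_arrays(valid_ds)
    if Ytr.shape[1:] != Yva.shape[1:]:
        raise ValueError("train and validation datasets disagree on geometry or k")
    trainable = model.trainable_names(cfg.level)
    eval_interval = cfg.eval_interval or max(1, math.ceil(Xtr.shape[0] / cfg.batch_size))
    history = _train_loop(
        model, trainable, Xtr, Ytr, Xva, Yva,
        lr=cfg.learning_rate, batch_size=cfg.batch_size, max_steps=cfg.max_steps,
        delta=cfg.early_stop_delta, patience=cfg.early_stop_patience,
        eval_interval=eval_interval, seed=seed, valid_loss_fn=valid_loss_fn,
    )
    return model, history


def pretrain_surrogate_trunk(
    train_ds: DatasetSplit,
    valid_ds: DatasetSplit,
    cfg: PrepConfig,
    C: int = 64,
    n_blocks: int = 2,
    steps: int = 300,
    learning_rate: float = 5e-3,
    batch_size: int = 16,
    seed: int = 0,
) -> tuple[SurrogateTrunk, TrainingHistory]:
    """Train a surrogate base model (all parameters) on a pretraining task.

    This stands in for the large pretrained sequence model: the returned
    trunk carries learned motif features that transfer to new track heads.
    """
    k0 = train_ds.targets().shape[2]
    trunk = SurrogateTrunk(cfg, C=C, n_blocks=n_blocks, seed=seed)
    tl = TLModel(trunk, HeadModel(C, k0, seed=seed + 1))
    Xtr, Ytr = _dataset_arrays(train_ds)
    Xva, Yva = _dataset_arrays(valid_ds)
    eval_interval = max(1, math.ceil(Xtr.shape[0] / batch_size))
    history = _train_loop(
        tl, set(tl.named_parameters()), Xtr, Ytr, Xva, Yva,
        lr=learning_rate, batch_size=batch_size, max_steps=steps,
        delta=0.0, patience=10**9, eval_interval=eval_interval, seed=seed,
    )
    return tl.trunk, history


# ------------------------------------------------------------------ checkpoints


def save_checkpoint(model: Module, path, config: dict | None = None) -> None:
    """Single-file parameter dump (.npz) with an optional config stanza."""
    import json

    arrays = model.state_dict()
    arrays["__config__"] = np.frombuffer(
        json.dumps(config or {}).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(model: Module, path) -> dict:
    import json

    with np.load(path) as data:
        config = json.loads(bytes(data["__config__"]).decode()) if "__config__" in data else {}
        model.load_state_dict({n: data[n] for n in data.files if n != "__config__"})
    return config
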