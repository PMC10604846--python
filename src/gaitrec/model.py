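"""The three-branch hybrid gait-recognition network and its training loop.

Architecture: a spatial-temporal graph-convolution encoder for raw skeleton
sequences (ten blocks, channel plan 3 -> 64x4 -> 128x3 -> 256x3, temporal
kernel 9, spatial kernel 3, temporal stride 2 at the channel-doubling
blocks, global average pooling, 1x1 convolution to a 64-vector), a stacked
LSTM encoder for joint-angle sequences (4 x 128 hidden, batch norm, dense to
16), and a single dense + ReLU encoder for the gait-parameter vector (16).
The branch outputs are concatenated, batch-normalized, dropped out and
mapped through a dense softmax classifier.  Training uses Adam with
cross-entropy loss plus an explicit L2 penalty and early stopping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .graph import JointGraph, build_joint_graph
from .nn import (
    Adam,
    BatchNorm,
    Dense,
    Dropout,
    GlobalAvgPool,
    GraphConv,
    LSTM,
    Parameter,
    ReLU,
    SubsampleTime,
    TemporalConv,
    cross_entropy_loss,
    softmax,
)

__all__ = [
    "HybridModelConfig",
    "TrainOptions",
    "EncoderOutputs",
    "HybridModel",
    "train_model",
    "loss",
]

ALL_BRANCHES = ("skeleton", "angles", "params")


@dataclass
class HybridModelConfig:
    """Layer plan for the hybrid network; defaults follow the reference plan."""

    n_classes: int = 6
    branches: tuple[str, ...] = ALL_BRANCHES
    # skeleton branch
    stgcn_channels: tuple[int, ...] = (64, 64, 64, 64, 128, 128, 128, 256, 256, 256)
    stgcn_strides: tuple[int, ...] = (1, 1, 1, 1, 2, 1, 1, 2, 1, 1)
    stgcn_out: int = 64
    temporal_kernel: int = 9
    residual: bool = True
    edge_importance: bool = False
    # angle branch
    n_angles: int = 25
    lstm_hidden: int = 128
    lstm_layers: int = 4
    lstm_out: int = 16
    # parameter branch
    n_params: int = 26
    ann_out: int = 16
    # head
    dropout: float = 0.5
    l2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError("need at least two classes")
        if not self.branches:
            raise ConfigurationError("at least one input branch must be active")
        unknown = [b for b in self.branches if b not in ALL_BRANCHES]
        if unknown:
            raise ConfigurationError(f"unknown branches {unknown}")
        if len(self.stgcn_channels) != len(self.stgcn_strides):
            raise ConfigurationError("channel plan and stride plan lengths differ")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.l2 < 0.0:
            raise ConfigurationError("l2 weight must be nonnegative")

    @classmethod
    def small(cls, n_classes: int, **overrides) -> "HybridModelConfig":
        """Reduced plan for CPU-scale experiments and tests."""
        defaults = dict(
            n_classes=n_classes,
            stgcn_channels=(8, 16),
            stgcn_strides=(1, 2),
            stgcn_out=16,
            lstm_hidden=24,
            lstm_layers=1,
            lstm_out=8,
            ann_out=16,
            dropout=0.1,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def fusion_dim(self) -> int:
        dims = {"skeleton": self.stgcn_out, "angles": self.lstm_out,
                "params": self.ann_out}
        return sum(dims[b] for b in self.branches)


@dataclass
class TrainOptions:
    """Optimization options: Adam, batch 50, up to 200 epochs, early stopping."""

    batch_size: int = 50
    max_epochs: int = 200
    patience: int = 20
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigurationError("batch size and epochs must be positive")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning rate must be positive")


@dataclass
class EncoderOutputs:
    """Per-branch encoded feature vectors (``None`` for inactive branches)."""

    f_s: np.ndarray | None = None
    f_a: np.ndarray | None = None
    f_p: np.ndarray | None = None


class _STGCNBlock:
    """One spatial graph convolution + temporal convolution block."""

    def __init__(self, n_in: int, n_out: int, graph: JointGraph, stride: int,
                 cfg: HybridModelConfig, rng: np.random.Generator, name: str):
        self.gcn = GraphConv(n_in, n_out, graph.adjacency, rng, f"{name}.gcn",
                             learnable_mask=cfg.edge_importance)
        self.bn1 = BatchNorm((n_out,), axes=(0, 1, 2), name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.tcn = TemporalConv(n_out, cfg.temporal_kernel, stride, rng,
                                f"{name}.tcn")
        self.bn2 = BatchNorm((n_out,), axes=(0, 1, 2), name=f"{name}.bn2")
        self.relu2 = ReLU()
        self.residual: list | None = None
        if cfg.residual:
            if n_in == n_out and stride == 1:
                self.residual = []
            else:
                self.residual = [SubsampleTime(stride),
                                 Dense(n_in, n_out, rng, f"{name}.res")]
        self.layers = [self.gcn, self.bn1, self.tcn, self.bn2]
        if self.residual:
            self.layers.extend(l for l in self.residual if l.params)
        self.params = [p for l in self.layers for p in l.params]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = self.gcn.forward(x, train)
        y = self.bn1.forward(y, train)
        y = self.relu1.forward(y, train)
        y = self.tcn.forward(y, train)
        y = self.bn2.forward(y, train)
        if self.residual is not None:
            r = x
            for layer in self.residual:
                r = layer.forward(r, train)
            y = y + r
        return self.relu2.forward(y, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dout)
        dres = d
        d = self.bn2.backward(d)
        d = self.tcn.backward(d)
        d = self.relu1.backward(d)
        d = self.bn1.backward(d)
        dx = self.gcn.backward(d)
        if self.residual is not None:
            r = dres
            for layer in reversed(self.residual):
                r = layer.backward(r)
            dx = dx + r
        return dx


class HybridModel:
    """Three-branch hybrid classifier over skeleton / angle / parameter views."""

    def __init__(self, config: HybridModelConfig, graph: JointGraph | None = None):
        self.config = config
        if graph is None:
            from .skeleton import default_joint_set
            graph = build_joint_graph(default_joint_set(),
                                      temporal_kernel=config.temporal_kernel)
        self.graph = graph
        rng = np.random.default_rng(config.seed)
        self.rng = rng
        cfg = config
        self.params: list[Parameter] = []

        if "skeleton" in cfg.branches:
            n = graph.n_joints
            self.data_bn = BatchNorm((n, 3), axes=(0, 1), name="data_bn")
            self.blocks = []
            n_in = 3
            for i, (n_out, stride) in enumerate(
                    zip(cfg.stgcn_channels, cfg.stgcn_strides)):
                self.blocks.append(
                    _STGCNBlock(n_in, n_out, graph, stride, cfg, rng, f"block{i}"))
                n_in = n_out
            self.pool = GlobalAvgPool()
            self.post_conv = Dense(n_in, cfg.stgcn_out, rng, "post_conv")
            self.post_relu = ReLU()
            self.params += [p for b in self.blocks for p in b.params]
            self.params += self.data_bn.params + self.post_conv.params

        if "angles" in cfg.branches:
            # input normalization per angle column over batch and time, the
            # counterpart of the skeleton branch's data BN (raw angles span
            # 0-180 degrees, which would saturate the LSTM gates)
            self.angles_bn = BatchNorm((cfg.n_angles,), axes=(0, 1),
                                       name="angles_bn")
            self.lstm = LSTM(cfg.n_angles, cfg.lstm_hidden, cfg.lstm_layers, rng)
            self.lstm_bn = BatchNorm((cfg.lstm_hidden,), axes=(0,), name="lstm_bn")
            self.lstm_fc = Dense(cfg.lstm_hidden, cfg.lstm_out, rng, "lstm_fc")
            self.lstm_relu = ReLU()
            self.params += (self.angles_bn.params + self.lstm.params +
                            self.lstm_bn.params + self.lstm_fc.params)

        if "params" in cfg.branches:
            self.ann_fc = Dense(cfg.n_params, cfg.ann_out, rng, "ann_fc")
            self.ann_relu = ReLU()
            self.params += self.ann_fc.params

        self.head_bn = BatchNorm((cfg.fusion_dim,), axes=(0,), name="head_bn")
        self.head_dropout = Dropout(cfg.dropout, rng)
        self.head_fc = Dense(cfg.fusion_dim, cfg.n_classes, rng, "head_fc")
        self.params += self.head_bn.params + self.head_fc.params

    # -- branch encoders ---------------------------------------------------

    def stgcn_encode(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Encode a ``(B, 3, T, N)`` (or unbatched ``(3, T, N)``) tensor."""
        if "skeleton" not in self.config.branches:
            raise ConfigurationError("skeleton branch is deactivated")
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        B, C, T, N = x.shape
        if C != 3 or N != self.graph.n_joints:
            raise ValidationError(f"expected (B, 3, T, {self.graph.n_joints}), "
                                  f"got {x.shape}")
        if T < self.config.temporal_kernel:
            raise ValidationError(
                f"sequence too short for the temporal receptive field: "
                f"T={T}, need at least {self.config.temporal_kernel}")
        self._skel_shape = (B, C, T, N)
        y = x.transpose(0, 2, 3, 1)  # channel-last (B, T, N, 3)
        y = self.data_bn.forward(y, train)
        for block in self.blocks:
            y = block.forward(y, train)
        y = self.pool.forward(y, train)
        y = self.post_conv.forward(y, train)
        y = self.post_relu.forward(y, train)
        return y[0] if squeeze else y

    def _stgcn_backward(self, dout: np.ndarray) -> None:
        d = self.post_relu.backward(dout)
        d = self.post_conv.backward(d)
        d = self.pool.backward(d)
        for block in reversed(self.blocks):
            d = block.backward(d)
        self.data_bn.backward(d)

    def lstm_encode(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Encode a ``(B, T, A)`` (or unbatched ``(T, A)``) angle matrix."""
        if "angles" not in self.config.branches:
            raise ConfigurationError("angle branch is deactivated")
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        if x.shape[-1] != self.config.n_angles:
            raise ValidationError(
                f"expected {self.config.n_angles} angle columns, got {x.shape[-1]}")
        x = self.angles_bn.forward(x, train)
        h = self.lstm.forward(x, train)
        h = self.lstm_bn.forward(h, train)
        h = self.lstm_fc.forward(h, train)
        h = self.lstm_relu.forward(h, train)
        return h[0] if squeeze else h

    def _lstm_backward(self, dout: np.ndarray) -> None:
        d = self.lstm_relu.backward(dout)
        d = self.lstm_fc.backward(d)
        d = self.lstm_bn.backward(d)
        d = self.lstm.backward(d)
        self.angles_bn.backward(d)

    def ann_encode(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Encode a ``(B, P)`` (or unbatched length-P) parameter vector."""
        if "params" not in self.config.branches:
            raise ConfigurationError("parameter branch is deactivated")
        squeeze = x.ndim == 1
        if squeeze:
            x = x[None]
        if x.shape[-1] != self.config.n_params:
            raise ValidationError(
                f"expected {self.config.n_params} parameters, got {x.shape[-1]}")
        h = self.ann_fc.forward(x, train)
        h = self.ann_relu.forward(h, train)
        return h[0] if squeeze else h

    def _ann_backward(self, dout: np.ndarray) -> None:
        d = self.ann_relu.backward(dout)
        self.ann_fc.backward(d)

    # -- fusion / classification ------------------------------------------

    def fuse_and_classify(self, out: EncoderOutputs,
                          train: bool = False) -> np.ndarray:
        """Concatenate branch features, normalize, drop out, classify."""
        parts = []
        by_branch = {"skeleton": out.f_s, "angles": out.f_a, "params": out.f_p}
        for b in self.config.branches:
            if by_branch[b] is None:
                raise ValidationError(f"missing encoder output for branch {b!r}")
            v = by_branch[b]
            parts.append(v[None] if v.ndim == 1 else v)
        fused = np.concatenate(parts, axis=-1)
        h = self.head_bn.forward(fused, train)
        h = self.head_dropout.forward(h, train)
        logits = self.head_fc.forward(h, train)
        return softmax(logits)

    def _head_backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        d = self.head_fc.backward(dlogits)
        d = self.head_dropout.backward(d)
        d = self.head_bn.backward(d)
        splits: dict[str, np.ndarray] = {}
        offset = 0
        dims = {"skeleton": self.config.stgcn_out, "angles": self.config.lstm_out,
                "params": self.config.ann_out}
        for b in self.config.branches:
            splits[b] = d[..., offset:offset + dims[b]]
            offset += dims[b]
        return splits

    # -- full model --------------------------------------------------------

    def forward(self, views: dict[str, np.ndarray],
                train: bool = False) -> np.ndarray:
        """Probabilities for a batch of views keyed by branch name."""
        out = EncoderOutputs()
        for b in self.config.branches:
            if b not in views or views[b] is None:
                raise ValidationError(f"missing input view for active branch {b!r}")
        if "skeleton" in self.config.branches:
            out.f_s = self.stgcn_encode(views["skeleton"], train)
        if "angles" in self.config.branches:
            out.f_a = self.lstm_encode(views["angles"], train)
        if "params" in self.config.branches:
            out.f_p = self.ann_encode(views["params"], train)
        return self.fuse_and_classify(out, train)

    def backward(self, dlogits: np.ndarray) -> None:
        splits = self._head_backward(dlogits)
        if "skeleton" in splits:
            self._stgcn_backward(splits["skeleton"])
        if "angles" in splits:
            self._lstm_backward(splits["angles"])
        if "params" in splits:
            self._ann_backward(splits["params"])

    def regularized_weights(self) -> list[np.ndarray]:
        return [p.value for p in self.params if p.regularized]

    def loss_and_grad(self, views: dict[str, np.ndarray],
                      labels: np.ndarray) -> tuple[float, np.ndarray]:
        """Training-mode forward + backward; returns (loss, probabilities)."""
        probs = self.forward(views, train=True)
        B = probs.shape[0]
        onehot = np.eye(self.config.n_classes)[labels]
        total = cross_entropy_loss(onehot, probs, self.config.l2,
                                   self.regularized_weights())
        dlogits = (probs - onehot) / B
        self.backward(dlogits)
        if self.config.l2 > 0:
            for p in self.params:
                if p.regularized:
                    p.grad += self.config.l2 * p.value
        return total, probs

    def predict(self, views: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """Inference-mode class indices and probabilities."""
        probs = self.forward(views, train=False)
        if probs.ndim == 1:
            return int(np.argmax(probs)), probs
        return np.argmax(probs, axis=-1), probs

    # -- state -------------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value for p in self.params}
        for attr in self._bn_layers():
            state[f"{attr[0]}.running_mean"] = attr[1].running_mean
            state[f"{attr[0]}.running_var"] = attr[1].running_var
        return state

    def _bn_layers(self) -> list[tuple[str, BatchNorm]]:
        found: list[tuple[str, BatchNorm]] = []

        def scan(obj, prefix):
            if isinstance(obj, BatchNorm):
                found.append((prefix, obj))

        if "skeleton" in self.config.branches:
            scan(self.data_bn, "data_bn")
            for i, b in enumerate(self.blocks):
                scan(b.bn1, f"block{i}.bn1")
                scan(b.bn2, f"block{i}.bn2")
        if "angles" in self.config.branches:
            scan(self.angles_bn, "angles_bn")
            scan(self.lstm_bn, "lstm_bn")
        scan(self.head_bn, "head_bn")
        return found

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}

    def restore(self, snap: dict[str, np.ndarray]) -> None:
        for p in self.params:
            p.value[...] = snap[p.name]
        for name, bn in self._bn_layers():
            bn.running_mean[...] = snap[f"{name}.running_mean"]
            bn.running_var[...] = snap[f"{name}.running_var"]

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: config JSON plus named weight arrays."""
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in self.config.__dict__.items()}
        arrays = {k.replace(".", "__"): v for k, v in self.state_arrays().items()}
        np.savez(path, __config__=np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path, graph: JointGraph | None = None) -> "HybridModel":
        with np.load(path) as data:
            cfg_dict = json.loads(bytes(data["__config__"]).decode())
            for key in ("branches", "stgcn_channels", "stgcn_strides"):
                cfg_dict[key] = tuple(cfg_dict[key])
            model = cls(HybridModelConfig(**cfg_dict), graph)
            snap = {k.replace("__", "."): data[k] for k in data.files
                    if k != "__config__"}
        model.restore(snap)
        return model


def loss(y_true: np.ndarray, y_hat: np.ndarray, lam: float = 0.0,
         weights: list[np.ndarray] | None = None) -> float:
    """Cross-entropy loss with an explicit L2 penalty (see :mod:`gaitrec.nn`)."""
    return cross_entropy_loss(y_true, y_hat, lam, weights)


def _subset(views: dict[str, np.ndarray], idx: np.ndarray) -> dict[str, np.ndarray]:
    return {k: v[idx] for k, v in views.items() if v is not None}


def _evaluate(model: HybridModel, views: dict[str, np.ndarray],
              labels: np.ndarray, batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    n = len(labels)
    for start in range(0, n, batch_size):
        idx = np.arange(start, min(start + batch_size, n))
        probs = model.forward(_subset(views, idx), train=False)
        onehot = np.eye(model.config.n_classes)[labels[idx]]
        losses.append(cross_entropy_loss(onehot, probs, model.config.l2,
                                         model.regularized_weights()) * len(idx))
        correct += int((np.argmax(probs, axis=-1) == labels[idx]).sum())
    return float(np.sum(losses) / n), correct / n


def train_model(
    model: HybridModel,
    train_views: dict[str, np.ndarray],
    train_labels: np.ndarray,
    val_views: dict[str, np.ndarray] | None = None,
    val_labels: np.ndarray | None = None,
    opts: TrainOptions | None = None,
) -> pd.DataFrame:
    """Train with Adam + early stopping; returns the per-epoch history.

    Early stopping monitors validation loss with the configured patience and
    restores the best-validation weights; with no validation set the final
    weights are kept.  Fully deterministic given the option seed.
    """
    opts = opts or TrainOptions()
    if len(train_labels) == 0:
        raise ValidationError("empty training split")
    rng = np.random.default_rng(opts.seed)
    optimizer = Adam(model.params, lr=opts.learning_rate)
    history: list[dict] = []
    best_val = np.inf
    best_snap = None
    best_epoch = -1
    n = len(train_labels)
    for epoch in range(opts.max_epochs):
        order = rng.permutation(n)
        epoch_loss, correct = 0.0, 0
        for start in range(0, n, opts.batch_size):
            idx = order[start:start + opts.batch_size]
            optimizer.zero_grad()
            batch_loss, probs = model.loss_and_grad(
                _subset(train_views, idx), train_labels[idx])
            optimizer.step()
            epoch_loss += batch_loss * len(idx)
            correct += int((np.argmax(probs, axis=-1) == train_labels[idx]).sum())
        record = {
            "epoch": epoch,
            "train_loss": epoch_loss / n,
            "train_accuracy": correct / n,
        }
        if val_views is not None and val_labels is not None and len(val_labels):
            val_loss, val_acc = _evaluate(model, val_views, val_labels,
                                          opts.batch_size)
            record["val_loss"] = val_loss
            record["val_accuracy"] = val_acc
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_snap = model.snapshot()
                best_epoch = epoch
            elif epoch - best_epoch >= opts.patience:
                history.append(record)
                break
        history.append(record)
        if opts.verbose:
            print(f"epoch {epoch}: " + ", ".join(
                f"{k}={v:.4f}" for k, v in record.items() if k != "epoch"))
    if best_snap is not None:
        model.restore(best_snap)
    return pd.DataFrame(history)
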