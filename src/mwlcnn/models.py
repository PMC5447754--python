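"""The five convolutional classifier architectures and their training loop.

Five fixed architectures of increasing depth (CNN1..CNN5) map the 102 x 10
band-power matrix to class posteriors.  Every convolution is valid-padding
with stride 1 and a ReLU; pooling is average pooling; each stack ends in a
fully-connected ReLU layer of width 256 and a softmax output.  Default
filter counts are 15 / 25 / 40 in the first / second / third convolutional
group and can be overridden.

Training minimizes mean cross-entropy with one of the four optimizers
(Nesterov momentum, Adagrad, Adadelta, Adam) over shuffled mini-batches;
given a seed the whole run — initialization, shuffling, updates — is
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import (
    AvgPool2D,
    Conv2D,
    Dense,
    DivergenceError,
    Flatten,
    Network,
    OptimizerConfig,
    ReLU,
    make_optimizer,
)

__all__ = [
    "ARCH_IDS",
    "OPTIMIZER_IDS",
    "ArchitectureSpec",
    "build_architecture",
    "forward_shapes",
    "TrainedModel",
    "train",
    "predict_proba",
    "predict",
    "accuracy",
    "save_model",
    "load_model",
]

ARCH_IDS = ("CNN1", "CNN2", "CNN3", "CNN4", "CNN5")
OPTIMIZER_IDS = ("nm", "adagrad", "adadelta", "adam")

# Layer stacks: ("conv", kh, kw, group) with group indexing the filter-count
# triple, or ("pool", ph, pw).  The trailing FC-256 + softmax is implicit.
_STACKS: dict[str, tuple[tuple, ...]] = {
    "CNN1": (("conv", 3, 3, 0), ("pool", 4, 2)),
    "CNN2": (
        ("conv", 3, 3, 0),
        ("pool", 4, 2),
        ("conv", 4, 1, 1),
        ("pool", 2, 2),
        ("conv", 4, 1, 2),
    ),
    "CNN3": (
        ("conv", 3, 3, 0),
        ("conv", 1, 1, 0),
        ("pool", 4, 2),
        ("conv", 4, 1, 1),
        ("conv", 1, 1, 1),
        ("pool", 2, 2),
        ("conv", 2, 2, 2),
        ("conv", 1, 1, 2),
    ),
    "CNN4": (
        ("conv", 3, 3, 0),
        ("conv", 3, 3, 0),
        ("pool", 2, 2),
        ("conv", 4, 1, 1),
        ("conv", 5, 1, 1),
        ("pool", 2, 1),
        ("conv", 2, 2, 2),
        ("conv", 2, 2, 2),
    ),
    "CNN5": (
        ("conv", 3, 3, 0),
        ("conv", 3, 3, 0),
        ("conv", 3, 3, 0),
        ("pool", 4, 2),
        ("conv", 4, 1, 1),
        ("conv", 4, 1, 1),
        ("conv", 4, 1, 1),
        ("pool", 3, 1),
        ("conv", 2, 1, 2),
        ("conv", 2, 1, 2),
        ("conv", 2, 1, 2),
    ),
}

DEFAULT_FILTER_COUNTS = (15, 25, 40)
FC_WIDTH = 256


@dataclass(frozen=True)
class ArchitectureSpec:
    """A fully resolved architecture: layer stack, widths and class count."""

    arch_id: str
    n_classes: int
    input_shape: tuple[int, int] = (102, 10)
    filter_counts: tuple[int, int, int] = DEFAULT_FILTER_COUNTS
    fc_width: int = FC_WIDTH

    @property
    def stack(self) -> tuple[tuple, ...]:
        return _STACKS[self.arch_id]


def build_architecture(
    arch_id: str,
    n_classes: int,
    input_shape: tuple[int, int] = (102, 10),
    filter_counts: tuple[int, int, int] = DEFAULT_FILTER_COUNTS,
) -> ArchitectureSpec:
    """Resolve an architecture id to its layer specification.

    Raises for unknown ids and for input shapes under which some feature
    map would collapse below 1 x 1.
    """
    if arch_id not in _STACKS:
        raise ValueError(f"unknown architecture {arch_id!r}; choose from {ARCH_IDS}")
    if n_classes < 2:
        raise ValueError("need at least two classes")
    spec = ArchitectureSpec(arch_id, n_classes, tuple(input_shape), tuple(filter_counts))
    forward_shapes(spec)  # raises if any spatial dimension collapses
    return spec


def forward_shapes(spec: ArchitectureSpec) -> list[tuple[int, int, int]]:
    """(channels, height, width) after each conv/pool stage, input first."""
    h, w = spec.input_shape
    c = 1
    shapes = [(c, h, w)]
    for entry in spec.stack:
        if entry[0] == "conv":
            _, kh, kw, group = entry
            h, w = h - kh + 1, w - kw + 1
            c = spec.filter_counts[group]
        else:
            _, ph, pw = entry
            h, w = h // ph, w // pw
        if h < 1 or w < 1:
            raise ValueError(
                f"{spec.arch_id}: feature map collapses to {h}x{w} at {entry}"
            )
        shapes.append((c, h, w))
    return shapes


def _build_network(spec: ArchitectureSpec, rng: np.random.Generator) -> Network:
    layers = []
    c = 1
    h, w = spec.input_shape
    for entry in spec.stack:
        if entry[0] == "conv":
            _, kh, kw, group = entry
            out_c = spec.filter_counts[group]
            layers += [Conv2D(c, out_c, kh, kw, rng), ReLU()]
            c, h, w = out_c, h - kh + 1, w - kw + 1
        else:
            _, ph, pw = entry
            layers.append(AvgPool2D(ph, pw))
            h, w = h // ph, w // pw
    layers += [
        Flatten(),
        Dense(c * h * w, spec.fc_width, rng),
        ReLU(),
        Dense(spec.fc_width, spec.n_classes, rng),
    ]
    return Network(layers)


@dataclass
class TrainedModel:
    """A fitted network plus everything needed to reproduce or reuse it."""

    spec: ArchitectureSpec
    network: Network
    optimizer_config: OptimizerConfig
    seed: int
    loss_trace: np.ndarray
    train_accuracy_trace: np.ndarray
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None

    def training_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.loss_trace) + 1),
                "loss": self.loss_trace,
                "train_acc": self.train_accuracy_trace,
            }
        )


def _as_nchw(features: np.ndarray, spec: ArchitectureSpec) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    if x.ndim == 3:
        x = x[:, None, :, :]
    if x.ndim != 4 or x.shape[2:] != spec.input_shape:
        raise ValueError(
            f"features of shape {np.asarray(features).shape} do not match "
            f"architecture input {spec.input_shape}"
        )
    return x


def train(
    spec: ArchitectureSpec,
    features: np.ndarray,
    labels: np.ndarray,
    optimizer: OptimizerConfig = OptimizerConfig(),
    epochs_n: int = 100,
    batch_size: int = 32,
    seed: int = 0,
    standardize: bool = True,
) -> TrainedModel:
    """Fit an architecture by mini-batch cross-entropy minimization.

    With ``standardize`` (default) each of the input-matrix entries is
    z-scored using training-set statistics; raw band powers span orders of
    magnitude and unscaled inputs slow or destabilize the small learning
    rates used here.  The scaling is stored with the model and re-applied
    at prediction time.

    Raises :class:`~mwlcnn.nn.DivergenceError` when the loss goes
    non-finite, reporting the epoch.
    """
    x = _as_nchw(features, spec)
    y = np.asarray(labels, dtype=int)
    if len(x) != len(y):
        raise ValueError("features and labels disagree in length")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must cover at least two classes")
    if not np.isfinite(x).all():
        raise ValueError("features contain non-finite values")

    mean = std = None
    if standardize:
        mean = x.mean(axis=0)
        std = x.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        x = (x - mean) / std

    rng = np.random.default_rng(seed)
    net = _build_network(spec, rng)
    opt = make_optimizer(net.params, optimizer)
    n = len(x)
    losses, accs = [], []
    for epoch in range(epochs_n):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i0 in range(0, n, batch_size):
            idx = order[i0 : i0 + batch_size]
            loss = net.loss_and_grad(x[idx], y[idx])
            if not np.isfinite(loss):
                raise DivergenceError(epoch + 1)
            opt.step(net.grads)
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)
        accs.append(float((net.predict_proba(x).argmax(axis=1) == y).mean()))
    return TrainedModel(
        spec=spec,
        network=net,
        optimizer_config=optimizer,
        seed=seed,
        loss_trace=np.asarray(losses),
        train_accuracy_trace=np.asarray(accs),
        feature_mean=mean,
        feature_std=std,
    )


def predict_proba(model: TrainedModel, features: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Class posteriors, one row per epoch, rows summing to 1."""
    x = _as_nchw(features, model.spec)
    if model.feature_mean is not None:
        x = (x - model.feature_mean) / model.feature_std
    out = [model.network.predict_proba(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
    return np.concatenate(out) if out else np.empty((0, model.spec.n_classes))


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    return predict_proba(model, features).argmax(axis=1)


def accuracy(model: TrainedModel, features: np.ndarray, labels: np.ndarray) -> float:
    return float((predict(model, features) == np.asarray(labels)).mean())


def save_model(model: TrainedModel, path) -> None:
    """Single-file checkpoint: architecture, config and flat parameters."""
    header = {
        "arch_id": model.spec.arch_id,
        "n_classes": model.spec.n_classes,
        "input_shape": list(model.spec.input_shape),
        "filter_counts": list(model.spec.filter_counts),
        "fc_width": model.spec.fc_width,
        "optimizer": model.optimizer_config.__dict__,
        "seed": model.seed,
    }
    arrays = {f"param_{i}": p for i, p in enumerate(model.network.params)}
    arrays["loss_trace"] = model.loss_trace
    arrays["train_accuracy_trace"] = model.train_accuracy_trace
    if model.feature_mean is not None:
        arrays["feature_mean"] = model.feature_mean
        arrays["feature_std"] = model.feature_std
    np.savez(path, header=json.dumps(header), **arrays)


def load_model(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        spec = ArchitectureSpec(
            arch_id=header["arch_id"],
            n_classes=header["n_classes"],
            input_shape=tuple(header["input_shape"]),
            filter_counts=tuple(header["filter_counts"]),
            fc_width=header["fc_width"],
        )
        net = _build_network(spec, np.random.default_rng(0))
        params = [data[f"param_{i}"] for i in range(len(net.params))]
        net.set_state(params)
        return TrainedModel(
            spec=spec,
            network=net,
            optimizer_config=OptimizerConfig(**header["optimizer"]),
            seed=header["seed"],
            loss_trace=data["loss_trace"],
            train_accuracy_trace=data["train_accuracy_trace"],
            feature_mean=data["feature_mean"] if "feature_mean" in data else None,
            feature_std=data["feature_std"] if "feature_std" in data else None,
        )
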