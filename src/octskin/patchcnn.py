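"""The configurable patch-classification CNN: count, build, train, predict.

The architecture family is fixed at three convolution + pooling blocks
followed by two fully connected layers (ReLU after each convolution and
after FC1, dropout after FC1, softmax output).  Everything else — kernel
sizes, filter counts, pooling kernels/strides/types, the per-layer pooling
output-rounding convention, FC1 width — is configuration, so the shipped
presets (``cnn-gs-skin``, ``cnn-gs-baseline``) and all the intermediate
tuning variants are instances of one :class:`ModelConfig`.

``count_parameters`` is closed-form and exact; ``build_model`` constructs a
network whose introspected parameter total always equals it.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import _nn
from .patchset import PatchSet

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "TrainReport",
    "PatchCNN",
    "load_preset",
    "preset_names",
    "count_parameters",
    "build_model",
    "train",
    "predict_batch",
    "predict_parallel",
]

_LOSSES = ("categorical_crossentropy", "kl_divergence")


@dataclass(frozen=True)
class ModelConfig:
    """Full architecture + training description of one patch classifier."""

    input_size: int = 55
    conv_kernels: tuple[int, int, int] = (3, 3, 3)
    conv_filters: tuple[int, int, int] = (8, 16, 16)
    conv_padding: tuple[str, str, str] = ("valid", "valid", "valid")
    pool_kernels: tuple[int, int, int] = (2, 2, 2)
    pool_strides: tuple[int, int, int] = (2, 2, 2)
    pool_types: tuple[str, str, str] = ("max", "avg", "avg")
    pool_rounding: tuple[str, str, str] = ("floor", "floor", "floor")
    fc1_units: int = 32
    dropout_rate: float = 0.1
    n_outputs: int = 4
    loss: str = "categorical_crossentropy"
    learning_rate: float = 1e-3
    batch_size: int = 512
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        for f in ("conv_kernels", "conv_filters", "conv_padding", "pool_kernels",
                  "pool_strides", "pool_types", "pool_rounding"):
            object.__setattr__(self, f, tuple(getattr(self, f)))
            if len(getattr(self, f)) != 3:
                raise ValueError(f"{f} must list exactly 3 entries (3 conv blocks)")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.loss not in _LOSSES:
            raise ValueError(f"loss must be one of {_LOSSES}")

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def preset_names() -> list[str]:
    files = resources.files("octskin").joinpath("presets")
    return sorted(p.name[: -len(".yaml")] for p in files.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> ModelConfig:
    """Load a shipped preset (e.g. ``cnn-gs-skin``, ``cnn-gs-baseline``)."""
    ref = resources.files("octskin").joinpath(f"presets/{name}.yaml")
    if not ref.is_file():
        raise ValueError(f"unknown preset {name!r}; available: {preset_names()}")
    return ModelConfig.from_dict(yaml.safe_load(ref.read_text()))


def _propagate_sizes(config: ModelConfig) -> list[int]:
    """Spatial size after each conv/pool layer; raises naming the layer."""
    sizes = []
    n = config.input_size
    for i in range(3):
        n = _nn.conv_output_size(n, config.conv_kernels[i], config.conv_padding[i])
        if n < 1:
            raise ValueError(f"conv{i + 1} output size {n} < 1")
        sizes.append(n)
        n = _nn.pool_output_size(n, config.pool_kernels[i], config.pool_strides[i], config.pool_rounding[i])
        if n < 1:
            raise ValueError(f"pool{i + 1} output size {n} < 1")
        sizes.append(n)
    return sizes


def count_parameters(config: ModelConfig) -> int:
    """Exact trainable parameter count of the configured network.

    Sum over convolutions of ``(k^2 * c_in + 1) * c_out`` plus the two dense
    layers ``(flat + 1) * fc1`` and ``(fc1 + 1) * n_outputs``, with ``flat``
    obtained by propagating spatial sizes under the configured padding and
    pooling-rounding conventions.
    """
    sizes = _propagate_sizes(config)
    total = 0
    c_in = 1
    for i in range(3):
        k, c_out = config.conv_kernels[i], config.conv_filters[i]
        total += (k * k * c_in + 1) * c_out
        c_in = c_out
    flat = sizes[-1] * sizes[-1] * config.conv_filters[-1]
    total += (flat + 1) * config.fc1_units
    total += (config.fc1_units + 1) * config.n_outputs
    return total


class PatchCNN:
    """A built network handle: seeded weights, forward pass, (de)serialization."""

    def __init__(self, config: ModelConfig):
        self.config = config
        sizes = _propagate_sizes(config)  # validates geometry
        rng = np.random.default_rng(config.seed)
        layers: list[_nn.Layer] = []
        c_in = 1
        for i in range(3):
            conv = _nn.Conv2D(c_in, config.conv_filters[i], config.conv_kernels[i],
                              config.conv_padding[i], rng, name=f"conv{i + 1}")
            conv.need_dx = i > 0  # no gradient needed w.r.t. the input image
            layers.append(conv)
            layers.append(_nn.ReLU())
            layers.append(_nn.Pool2D(config.pool_types[i], config.pool_kernels[i],
                                     config.pool_strides[i], config.pool_rounding[i],
                                     name=f"pool{i + 1}"))
            c_in = config.conv_filters[i]
        layers.append(_nn.Flatten())
        flat = sizes[-1] * sizes[-1] * config.conv_filters[-1]
        layers.append(_nn.Dense(flat, config.fc1_units, rng, name="fc1"))
        layers.append(_nn.ReLU())
        self.dropout = _nn.Dropout(config.dropout_rate)
        layers.append(self.dropout)
        layers.append(_nn.Dense(config.fc1_units, config.n_outputs, rng, name="fc2"))
        self.layers = layers

    # -- introspection ----------------------------------------------------
    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    # -- forward ----------------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def predict_proba(self, patches: np.ndarray, batch_size: int | None = None) -> np.ndarray:
        """Softmax probabilities, shape (n, n_outputs), processed in chunks."""
        patches = np.asarray(patches, dtype=np.float32)
        if patches.ndim == 3:
            patches = patches[:, None]  # add channel axis
        if patches.shape[-1] != self.config.input_size:
            raise ValueError(
                f"patch size {patches.shape[-2:]} does not match model input "
                f"{self.config.input_size}"
            )
        bs = batch_size or self.config.batch_size
        out = np.empty((patches.shape[0], self.config.n_outputs), dtype=np.float32)
        for lo in range(0, patches.shape[0], bs):
            chunk = patches[lo : lo + bs]
            out[lo : lo + chunk.shape[0]] = _nn.softmax(self.forward_logits(chunk))
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write weights (.npz) plus a YAML config sidecar."""
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path, config=yaml.safe_dump(self.config.to_dict()), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "PatchCNN":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"model checkpoint not found: {path}")
        with np.load(path, allow_pickle=False) as data:
            config = ModelConfig.from_dict(yaml.safe_load(str(data["config"])))
            model = cls(config)
            for i, p in enumerate(model.parameters()):
                p[...] = data[f"p{i}"]
        return model

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p[...] = w


def build_model(config: ModelConfig) -> PatchCNN:
    """Construct the network; its introspected total equals count_parameters."""
    model = PatchCNN(config)
    assert model.n_params == count_parameters(config)
    return model


@dataclass
class TrainReport:
    """Per-epoch history of one early-stopped training run."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    stopping_epoch: int = 0
    best_epoch: int = 0
    test_accuracy: float | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _onehot(labels: np.ndarray, n_outputs: int) -> np.ndarray:
    out = np.zeros((labels.shape[0], n_outputs), dtype=np.float32)
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out


def evaluate(model: PatchCNN, patchset: PatchSet) -> tuple[float, float]:
    """Loss and argmax accuracy of a labeled patchset."""
    if patchset.labels is None:
        raise ValueError("labeled patchset required")
    probs = model.predict_proba(patchset.patches)
    onehot = _onehot(patchset.labels, model.config.n_outputs)
    loss = _nn.cross_entropy(probs, onehot)
    acc = float((probs.argmax(axis=1) == patchset.labels).mean())
    return loss, acc


def train(
    model: PatchCNN,
    train_set: PatchSet,
    val_set: PatchSet,
    config: ModelConfig | None = None,
) -> TrainReport:
    """RMSprop training with early stopping on validation loss.

    Labels are one-hot encoded to ``n_outputs`` classes (the reserved fourth
    class is never positive, so cross-entropy is unaffected).  Training stops
    once the validation loss has not improved for ``patience`` epochs; the
    best-validation weights are restored before returning.
    """
    config = config or model.config
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("empty train or validation set")
    if train_set.labels is None or val_set.labels is None:
        raise ValueError("labeled patchsets required")

    x = np.asarray(train_set.patches, dtype=np.float32)[:, None]
    y = _onehot(train_set.labels, config.n_outputs)
    n = x.shape[0]
    rng = np.random.default_rng(config.seed + 1)
    model.dropout.rng = rng
    opt = _nn.RMSprop(model.parameters(), lr=config.learning_rate)

    report = TrainReport(seed=config.seed)
    best_val = np.inf
    best_weights = model.get_weights()
    since_best = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward_logits(xb, train=True)
            probs = _nn.softmax(logits)
            losses.append(_nn.cross_entropy(probs, yb) * idx.size)
            correct += int((probs.argmax(axis=1) == yb.argmax(axis=1)).sum())
            model.backward((probs - yb) / idx.size)
            opt.step(model.gradients())
        report.train_loss.append(sum(losses) / n)
        report.train_acc.append(correct / n)

        val_loss, val_acc = evaluate(model, val_set)
        report.val_loss.append(val_loss)
        report.val_acc.append(val_acc)
        logger.info(
            "epoch %d: train loss %.4f acc %.4f | val loss %.4f acc %.4f",
            epoch, report.train_loss[-1], report.train_acc[-1], val_loss, val_acc,
        )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_weights = model.get_weights()
            report.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    report.stopping_epoch = epoch
    model.set_weights(best_weights)
    model.dropout.rng = None
    return report


def predict_batch(model: PatchCNN, patches: PatchSet | np.ndarray) -> np.ndarray:
    """Per-patch softmax probability vectors, order-aligned with centers."""
    arr = patches.patches if isinstance(patches, PatchSet) else np.asarray(patches)
    return model.predict_proba(arr)


def _worker_predict(model_path: str, patches: np.ndarray) -> np.ndarray:
    model = PatchCNN.load(model_path)
    return model.predict_proba(patches)


def predict_parallel(
    model_path: str | Path,
    patches: PatchSet | np.ndarray,
    n_workers: int = 1,
) -> np.ndarray:
    """Multi-process inference: contiguous chunks, one model load per worker.

    Output is identical (within float rounding) to :func:`predict_batch`;
    with ``n_workers=1`` the model is loaded in-process.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    model_path = Path(model_path)
    if not model_path.exists():
        raise FileNotFoundError(f"model checkpoint not found: {model_path}")
    arr = patches.patches if isinstance(patches, PatchSet) else np.asarray(patches)
    n = arr.shape[0]
    if n_workers > max(n, 1):
        logger.warning("capping n_workers=%d to %d available chunks", n_workers, max(n, 1))
        n_workers = max(n, 1)
    if n_workers == 1:
        return _worker_predict(str(model_path), arr)
    chunks = np.array_split(arr, n_workers)
    with ProcessPoolExecutor(max_workers=n_workers) as pool:
        parts = list(pool.map(_worker_predict, [str(model_path)] * len(chunks), chunks))
    return np.concatenate(parts, axis=0)
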