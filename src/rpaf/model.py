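"""Residual CNN classifier for recurrence-plot images or raw ECG segments.

Architecture: a convolutional stem, three residual blocks (the first with
2x2 kernels, the other two with 3x3), global average pooling, and two fully
connected layers producing two class scores. The ``rp2d`` variant consumes
S x S recurrence-density images; ``raw1d`` consumes the denoised 1-D
segment directly through the same topology with height-1 kernels.

Training follows the usual small-scale protocol: softmax cross-entropy,
Adam, mini-batches, early stopping on validation loss with weight restore,
and stratified record-disjoint k-fold cross-validation.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold

from rpaf import _nn
from rpaf.ecg import ParameterError
from rpaf.evaluate import EvalMetrics, confusion, metrics, roc_auc

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "ResNetClassifier",
    "build_model",
    "train",
    "predict",
    "crossvalidate",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    """Topology of the classifier.

    ``input_size`` is the image side for ``rp2d`` or the series length for
    ``raw1d``. Kernels are (2,2)/(3,3)/(3,3) across the three blocks;
    ``raw1d`` uses the same lengths as 1-D kernels.
    """

    variant: str = "rp2d"
    input_size: int = 64
    stem_channels: int = 16
    block_channels: tuple[int, int, int] = (16, 32, 64)
    kernel_sizes: tuple[int, int, int] = (2, 3, 3)
    fc_width: int = 32
    n_classes: int = 2
    stem_stride: int = 2

    def __post_init__(self) -> None:
        if self.variant not in ("rp2d", "raw1d"):
            raise ParameterError("variant must be 'rp2d' or 'raw1d'")
        if len(self.block_channels) != 3 or len(self.kernel_sizes) != 3:
            raise ParameterError("exactly three residual blocks are required")


@dataclass
class TrainConfig:
    """Optimisation protocol."""

    lr: float = 1e-5
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0
    folds: int = 5

    def __post_init__(self) -> None:
        if not self.lr > 0:
            raise ParameterError("learning rate must be > 0")
        if self.patience < 1:
            raise ParameterError("patience must be >= 1")


class ResNetClassifier:
    """Thin container around the layer stack; holds config and history."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        oned = config.variant == "raw1d"

        def kern(k: int) -> tuple[int, int]:
            return (1, k) if oned else (k, k)

        stem_k = kern(3)
        stride = config.stem_stride
        c = config.stem_channels
        b1, b2, b3 = config.block_channels
        k1, k2, k3 = config.kernel_sizes
        self.stem = _nn.Sequential(
            _nn.Conv2d(1, c, stem_k, stride=stride, rng=rng),
            _nn.BatchNorm2d(c),
            _nn.ReLU(),
        )
        self.blocks = [
            _nn.ResidualBlock(c, b1, kern(k1), stride=1, rng=rng),
            _nn.ResidualBlock(b1, b2, kern(k2), stride=2, rng=rng),
            _nn.ResidualBlock(b2, b3, kern(k3), stride=2, rng=rng),
        ]
        self.head = _nn.Sequential(
            _nn.GlobalAvgPool(),
            _nn.Linear(b3, config.fc_width, rng=rng),
            _nn.ReLU(),
            # near-zero head keeps the untrained classifier at chance
            _nn.Linear(config.fc_width, config.n_classes, rng=rng,
                       init_scale=0.01),
        )
        self.net = _nn.Sequential(self.stem, *self.blocks, self.head)
        self.history: dict[str, list[float]] = {}

    # -- plumbing ---------------------------------------------------------

    def _to_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if self.config.variant == "rp2d":
            if x.ndim == 2:
                x = x[None]
            if x.ndim == 3:
                x = x[:, None, :, :]
            if x.shape[-1] != self.config.input_size or x.shape[-2] != self.config.input_size:
                raise ParameterError(
                    f"expected {self.config.input_size}x{self.config.input_size} images, "
                    f"got {x.shape[-2]}x{x.shape[-1]}"
                )
        else:
            if x.ndim == 1:
                x = x[None]
            if x.ndim == 2:
                x = x[:, None, None, :]
            if x.shape[-1] != self.config.input_size:
                raise ParameterError(
                    f"expected series of length {self.config.input_size}, got {x.shape[-1]}"
                )
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(self._to_batch(x), training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.net.walk() for p in layer.params.values())

    def summary(self) -> str:
        n = self.n_parameters()
        mb = n * 4 / 2**20  # at float32 storage
        return (f"ResNetClassifier(variant={self.config.variant}, "
                f"input={self.config.input_size}, params={n}, ~{mb:.2f} MB fp32)")

    def state(self) -> list[np.ndarray]:
        out = []
        for layer in self.net.walk():
            out.extend(np.copy(p) for p in layer.params.values())
            if isinstance(layer, _nn.BatchNorm2d):
                out.extend([layer.running_mean.copy(), layer.running_var.copy()])
        return out

    def load_state(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for layer in self.net.walk():
            for name in layer.params:
                layer.params[name][...] = next(it)
            if isinstance(layer, _nn.BatchNorm2d):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)


def build_model(config: ModelConfig | None = None, seed: int = 0) -> ResNetClassifier:
    """Construct the classifier with seed-reproducible initialisation."""
    return ResNetClassifier(config or ModelConfig(), seed=seed)


def predict(model: ResNetClassifier, inputs: np.ndarray,
            batch_size: int = 64) -> np.ndarray:
    """Class-1 (pre-AF) probability per input, batch order preserved."""
    x = model._to_batch(inputs)
    probs = []
    for i in range(0, x.shape[0], batch_size):
        logits = model.net.forward(x[i: i + batch_size], training=False)
        probs.append(_nn.softmax(logits)[:, 1])
    return np.concatenate(probs)


def train(
    model: ResNetClassifier,
    x_train: np.ndarray, y_train: np.ndarray,
    x_val: np.ndarray, y_val: np.ndarray,
    config: TrainConfig | None = None,
) -> ResNetClassifier:
    """Optimise with Adam + early stopping; returns the best-epoch model.

    History (per-epoch train/val loss and accuracy) lands in
    ``model.history``; the restored weights are those of the epoch with the
    lowest validation loss.
    """
    config = config or TrainConfig()
    y_train = np.asarray(y_train, dtype=int)
    y_val = np.asarray(y_val, dtype=int)
    if y_train.size == 0 or y_val.size == 0:
        raise ParameterError("training and validation sets must be non-empty")
    if np.unique(y_train).size < 2:
        raise ParameterError("training set must contain both classes")
    xt = model._to_batch(x_train)
    xv = model._to_batch(x_val)
    rng = np.random.default_rng(config.seed)
    opt = _nn.Adam(model.net, lr=config.lr)
    hist: dict[str, list[float]] = {k: [] for k in
                                    ("train_loss", "train_acc", "val_loss", "val_acc")}
    best_loss, best_state, best_epoch, bad = np.inf, model.state(), 0, 0
    n = xt.shape[0]
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i: i + config.batch_size]
            logits = model.net.forward(xt[idx], training=True)
            loss, grad = _nn.cross_entropy_grad(logits, y_train[idx])
            model.net.backward(grad)
            opt.step()
            ep_loss += loss * idx.size
            ep_correct += int((logits.argmax(axis=1) == y_train[idx]).sum())
        hist["train_loss"].append(ep_loss / n)
        hist["train_acc"].append(ep_correct / n)

        val_logits = model.net.forward(xv, training=False)
        val_loss, _ = _nn.cross_entropy_grad(val_logits, y_val)
        hist["val_loss"].append(val_loss)
        hist["val_acc"].append(float((val_logits.argmax(axis=1) == y_val).mean()))

        if val_loss < best_loss - 1e-12:
            best_loss, best_state, best_epoch, bad = val_loss, model.state(), _epoch, 0
        else:
            bad += 1
            if bad >= config.patience:
                break
    model.load_state(best_state)
    model.history = hist
    model.history["best_epoch"] = [best_epoch]
    return model


def crossvalidate(
    x: np.ndarray, y: np.ndarray,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    groups: np.ndarray | None = None,
) -> tuple[list[EvalMetrics], dict[str, tuple[float, float]]]:
    """Stratified, record-disjoint k-fold cross-validation.

    ``groups`` carries record ids so no record straddles folds; defaults to
    one group per sample. Returns per-fold metrics and a mean/std summary.
    """
    train_config = train_config or TrainConfig()
    model_config = model_config or ModelConfig()
    y = np.asarray(y, dtype=int)
    k = train_config.folds
    if k < 2:
        raise ParameterError("need k >= 2 folds")
    if min(np.bincount(y, minlength=2)) < k:
        raise ParameterError("each class needs at least k members")
    if groups is None:
        groups = np.arange(y.size)
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                    random_state=train_config.seed)
    fold_metrics: list[EvalMetrics] = []
    for fold, (tr, va) in enumerate(splitter.split(np.zeros_like(y), y, groups)):
        model = build_model(model_config, seed=train_config.seed + fold)
        train(model, x[tr], y[tr], x[va], y[va], train_config)
        p = predict(model, x[va])
        m = metrics(confusion(y[va], (p >= 0.5).astype(int)))
        try:
            m.auc = roc_auc(p, y[va])[0]
        except ParameterError:
            m.auc = None
        fold_metrics.append(m)
    summary = {}
    for key in ("accuracy", "precision", "recall", "f1", "auc"):
        vals = [getattr(m, key) for m in fold_metrics if getattr(m, key) is not None]
        if vals:
            summary[key] = (float(np.mean(vals)), float(np.std(vals)))
    return fold_metrics, summary


def save_model(model: ResNetClassifier, path) -> None:
    """Single-file checkpoint: config + weights + training history."""
    meta = json.dumps({"config": asdict(model.config),
                       "history": model.history})
    arrays = {f"w{i}": a for i, a in enumerate(model.state())}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> ResNetClassifier:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg = ModelConfig(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in meta["config"].items()})
        model = ResNetClassifier(cfg)
        n = len([k for k in z.files if k.startswith("w")])
        model.load_state([z[f"w{i}"] for i in range(n)])
        model.history = meta["history"]
    return model
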