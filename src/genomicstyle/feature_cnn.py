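"""The feature-extraction CNN: species-classification pre-training.

The network consumes a 4 x 1024 one-hot DNA window and stacks eight modules
of (convolution -> batch normalization -> ReLU -> max pooling), followed by
global average pooling and a fully connected layer that scores species
classes.  It is trained once, with softmax cross-entropy, on windows drawn
from labeled genomes; afterwards only the convolutional trunk is used — the
per-layer feature maps feed the Gram-matrix (style) computation, and the
classification head is never read again.

"Layer l feature maps" throughout the package means the post-ReLU,
pre-pooling activations of conv module ``l`` (1-based), the largest
activation grid each module produces.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .seqio import one_hot_encode
from .synthetic import LabeledDataset

CHECKPOINT_FORMAT = "genomicstyle-checkpoint-1"

#: Default module widths: 64 filters each; the first filter spans 8 bp (a
#: position-weight-matrix-scale motif detector), deeper filters span 4
#: feature positions; every module halves the length with width-2 pooling,
#: taking 1024 positions down to 4 before global average pooling.
DEFAULT_N_FILTERS = 64
DEFAULT_FILTER_SIZES = (8, 4, 4, 4, 4, 4, 4, 4)


@dataclass(frozen=True)
class ConvModuleSpec:
    """One conv module: ``n_filters`` filters of width ``filter_size``, then
    max pooling of width ``pool_size``."""

    n_filters: int
    filter_size: int
    pool_size: int = 2

    def __post_init__(self) -> None:
        if min(self.n_filters, self.filter_size, self.pool_size) < 1:
            raise ValueError("all ConvModuleSpec fields must be >= 1")


@dataclass(frozen=True)
class FeatureCnnConfig:
    """Architecture + initialization seed for the feature-extraction CNN."""

    modules: tuple[ConvModuleSpec, ...]
    n_classes: int
    input_length: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.modules) != 8:
            raise ValueError("the feature-extraction CNN stacks exactly 8 conv modules")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        length = self.input_length
        for i, mod in enumerate(self.modules, start=1):
            length //= mod.pool_size
            if length < 1:
                raise ValueError(
                    f"spatial size collapses to 0 after module {i}; "
                    "reduce pool sizes or increase input_length"
                )

    @classmethod
    def default(cls, n_classes: int, seed: int = 0, n_filters: int = DEFAULT_N_FILTERS,
                input_length: int = 1024) -> "FeatureCnnConfig":
        mods = tuple(
            ConvModuleSpec(n_filters=n_filters, filter_size=d, pool_size=2)
            for d in DEFAULT_FILTER_SIZES
        )
        return cls(modules=mods, n_classes=n_classes, input_length=input_length, seed=seed)

    def to_dict(self) -> dict:
        return {
            "modules": [
                {"n_filters": m.n_filters, "filter_size": m.filter_size,
                 "pool_size": m.pool_size}
                for m in self.modules
            ],
            "n_classes": self.n_classes,
            "input_length": self.input_length,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureCnnConfig":
        return cls(
            modules=tuple(ConvModuleSpec(**m) for m in d["modules"]),
            n_classes=d["n_classes"],
            input_length=d["input_length"],
            seed=d["seed"],
        )


@dataclass
class TrainingLogEntry:
    epoch: int
    train_loss: float
    holdout_accuracy: float


class FeatureCnn:
    """The eight-module CNN with GAP + fully connected classification head.

    ``class_names`` maps head outputs back to species labels once the model
    has been trained; it is None for a freshly initialized model.
    """

    def __init__(self, config: FeatureCnnConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.convs: list[_nn.Conv1d] = []
        self.bns: list[_nn.BatchNorm1d] = []
        self.pools: list[_nn.MaxPool1d] = []
        n_in = 4
        for mod in config.modules:
            self.convs.append(_nn.Conv1d(n_in, mod.n_filters, mod.filter_size, rng))
            self.bns.append(_nn.BatchNorm1d(mod.n_filters))
            self.pools.append(_nn.MaxPool1d(mod.pool_size))
            n_in = mod.n_filters
        self.gap = _nn.GlobalAvgPool()
        self.fc = _nn.Dense(n_in, config.n_classes, rng)
        self.relu = _nn.ReLU()
        self.class_names: list[str] | None = None

    # ---- forward ---------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != 4 or x.shape[2] != self.config.input_length:
            raise ValueError(
                f"expected windows of shape (4, {self.config.input_length}), got {x.shape[1:]}"
            )
        return x

    def forward(
        self, x: np.ndarray, train: bool = False, upto_layer: int | None = None
    ) -> tuple[np.ndarray | None, list[np.ndarray]]:
        """Run the trunk (and head unless ``upto_layer`` stops early).

        Returns ``(logits, feature_maps)`` where ``feature_maps[l-1]`` is the
        post-ReLU, pre-pool activation of module ``l`` with shape
        (batch, n_filters, length).  With ``upto_layer=l`` only modules
        1..l are evaluated and logits is None.
        """
        x = self._check_input(x)
        relus = [_nn.ReLU() for _ in self.convs] if train else None
        feature_maps: list[np.ndarray] = []
        h = np.ascontiguousarray(x.transpose(0, 2, 1))  # (B, L, C) internally
        for i, (conv, bn, pool) in enumerate(zip(self.convs, self.bns, self.pools)):
            h = conv.forward(h, train)
            h = bn.forward(h, train)
            relu = relus[i] if train else self.relu
            h = relu.forward(h, train)
            feature_maps.append(h.transpose(0, 2, 1))  # expose as (B, N_l, M_l)
            if upto_layer is not None and i + 1 == upto_layer:
                return None, feature_maps
            h = pool.forward(h, train)
        pooled = self.gap.forward(h, train)
        logits = self.fc.forward(pooled, train)
        if train:
            self._relus = relus
        return logits, feature_maps

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.fc.backward(dlogits)
        dy = self.gap.backward(dy)
        for conv, bn, relu, pool in zip(
            reversed(self.convs), reversed(self.bns),
            reversed(self._relus), reversed(self.pools),
        ):
            dy = pool.backward(dy)
            dy = relu.backward(dy)
            dy = bn.backward(dy)
            dy = conv.backward(dy)

    def layers(self) -> list[_nn.Layer]:
        out: list[_nn.Layer] = []
        for conv, bn in zip(self.convs, self.bns):
            out.extend([conv, bn])
        out.append(self.fc)
        return out

    def predict_classes(self, x: np.ndarray) -> np.ndarray:
        """Argmax class per window; ties resolve to the lowest class index."""
        logits, _ = self.forward(x, train=False)
        return np.asarray(logits).argmax(axis=1)


def build_model(config: FeatureCnnConfig) -> FeatureCnn:
    """Deterministically initialize an untrained model from its config."""
    return FeatureCnn(config)


def encode_dataset(dataset: LabeledDataset, input_length: int) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """One-hot encode a labeled dataset, zero-padding short sequences.

    Returns (windows, class_indices, class_names); class names are the sorted
    unique labels.
    """
    class_names = sorted(set(dataset.labels))
    index = {c: i for i, c in enumerate(class_names)}
    X = np.zeros((len(dataset), 4, input_length), dtype=np.float32)
    y = np.empty(len(dataset), dtype=np.int64)
    for i, (seq, lab) in enumerate(zip(dataset.sequences, dataset.labels)):
        if seq.length > input_length:
            raise ValueError(
                f"sequence {seq.id!r} is longer ({seq.length}) than input_length {input_length}"
            )
        X[i, :, : seq.length] = one_hot_encode(seq)
        y[i] = index[lab]
    return X, y, class_names


def train(
    model: FeatureCnn,
    data: LabeledDataset,
    epochs: int = 20,
    batch_size: int = 64,
    seed: int = 0,
    learning_rate: float = 1e-3,
    holdout_fraction: float = 0.1,
) -> tuple[FeatureCnn, list[TrainingLogEntry]]:
    """Pre-train the CNN on species classification with Adam.

    A stratified ``holdout_fraction`` split is scored after every epoch; the
    log records (epoch, mean train loss, holdout accuracy).  ``epochs=0``
    returns the model unchanged with an empty log.
    """
    from sklearn.model_selection import train_test_split

    X, y, class_names = encode_dataset(data, model.config.input_length)
    if len(class_names) < 2:
        raise ValueError("training data must contain at least 2 classes")
    model.class_names = class_names
    if epochs == 0:
        return model, []
    rng = np.random.default_rng(seed)
    X_tr, X_ho, y_tr, y_ho = train_test_split(
        X, y, test_size=holdout_fraction, stratify=y,
        random_state=int(rng.integers(2**31)),
    )
    opt = _nn.Adam(model.layers(), lr=learning_rate)
    log: list[TrainingLogEntry] = []
    n = X_tr.shape[0]
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            if idx.size < 2:
                continue  # batch norm needs more than one example
            logits, _ = model.forward(X_tr[idx], train=True)
            loss, dlogits = _nn.cross_entropy(logits, y_tr[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        acc = holdout_accuracy(model, X_ho, y_ho)
        log.append(TrainingLogEntry(epoch, float(np.mean(losses)), acc))
    return model, log


def holdout_accuracy(model: FeatureCnn, X: np.ndarray, y: np.ndarray,
                     batch_size: int = 256) -> float:
    correct = 0
    for start in range(0, X.shape[0], batch_size):
        pred = model.predict_classes(X[start : start + batch_size])
        correct += int((pred == y[start : start + batch_size]).sum())
    return correct / X.shape[0]


def extract_feature_maps(
    model: FeatureCnn, window: np.ndarray, upto_layer: int | None = None
) -> list[np.ndarray]:
    """Per-layer feature maps F(l) for one 4 x input_length window.

    Batch norm runs in inference mode (stored running statistics).  Returns a
    list of (N_l, M_l) arrays, one per evaluated module; entries are >= 0
    because the tap is post-ReLU.
    """
    window = np.asarray(window, dtype=np.float32)
    if window.ndim != 2:
        raise ValueError("extract_feature_maps expects a single 4 x L window")
    _, maps = model.forward(window[None], train=False, upto_layer=upto_layer)
    return [m[0] for m in maps]


def write_training_log(path: str | Path, log: list[TrainingLogEntry]) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\ttrain_loss\tholdout_accuracy\n")
        for entry in log:
            fh.write(f"{entry.epoch}\t{entry.train_loss:.6f}\t{entry.holdout_accuracy:.4f}\n")


# ---- checkpoints ----------------------------------------------------------


def save_checkpoint(model: FeatureCnn, path: str | Path) -> None:
    """Write config + weights + batch-norm running statistics to one archive."""
    arrays: dict[str, np.ndarray] = {}
    for i, (conv, bn) in enumerate(zip(model.convs, model.bns)):
        arrays[f"conv{i}_W"] = conv.W
        arrays[f"conv{i}_b"] = conv.b
        arrays[f"bn{i}_gamma"] = bn.gamma
        arrays[f"bn{i}_beta"] = bn.beta
        arrays[f"bn{i}_running_mean"] = bn.running_mean
        arrays[f"bn{i}_running_var"] = bn.running_var
    arrays["fc_W"] = model.fc.W
    arrays["fc_b"] = model.fc.b
    meta = {
        "format": CHECKPOINT_FORMAT,
        "config": model.config.to_dict(),
        "class_names": model.class_names,
    }
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        zf.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path: str | Path, expected_n_classes: int | None = None) -> FeatureCnn:
    """Rebuild a model from :func:`save_checkpoint` output.

    Forward outputs are bit-identical to the saved model on the same
    platform.  Raises a descriptive error for corrupted archives, unknown
    format versions, or an ``expected_n_classes`` mismatch.
    """
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            weights = np.load(io.BytesIO(zf.read("weights.npz")))
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"corrupted or unreadable checkpoint {path}: {exc}") from exc
    if meta.get("format") != CHECKPOINT_FORMAT:
        raise ValueError(
            f"checkpoint format {meta.get('format')!r} does not match {CHECKPOINT_FORMAT!r}"
        )
    config = FeatureCnnConfig.from_dict(meta["config"])
    if expected_n_classes is not None and config.n_classes != expected_n_classes:
        raise ValueError(
            f"checkpoint has n_classes={config.n_classes}, expected {expected_n_classes}"
        )
    model = FeatureCnn(config)
    for i, (conv, bn) in enumerate(zip(model.convs, model.bns)):
        conv.W[...] = weights[f"conv{i}_W"]
        conv.b[...] = weights[f"conv{i}_b"]
        bn.gamma[...] = weights[f"bn{i}_gamma"]
        bn.beta[...] = weights[f"bn{i}_beta"]
        bn.running_mean[...] = weights[f"bn{i}_running_mean"]
        bn.running_var[...] = weights[f"bn{i}_running_var"]
    model.fc.W[...] = weights["fc_W"]
    model.fc.b[...] = weights["fc_b"]
    model.class_names = meta.get("class_names")
    return model
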