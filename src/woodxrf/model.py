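"""The 1D-CNN species classifier: splitting, building, training, persistence.

Architecture (fixed topology, sizes configurable):
three blocks of ``conv1d -> batch norm -> ReLU -> max-pool(2)`` with filter
counts 32/64/128 and kernels 5/3/2, flattened into four dense layers of
512/256/128/64 units with ReLU and 60% dropout, and a softmax output over
the species vocabulary.  Training uses the Nadam optimizer at learning rate
1e-5, batch size 4, categorical crossentropy, a fixed epoch budget with no
early stopping, and a random 15% validation mask.

Everything is seeded: weight initialisation, the train/validation split,
batch order and dropout masks all derive deterministic child streams from
``CNNConfig.seed``, so a run is reproducible bit for bit on one machine.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .errors import (
    ArchitectureError,
    ConfigurationError,
    GridMismatchError,
    IntegrityError,
    StratificationError,
)
from .preprocess import FeatureGrid, LabeledDataset

__all__ = [
    "CNNConfig",
    "TrainingHistory",
    "WoodClassifier",
    "split",
    "build",
    "train",
    "save",
    "load",
]


@dataclass(frozen=True)
class CNNConfig:
    """Full hyperparameter record of the classifier."""

    conv_filters: tuple = (32, 64, 128)
    conv_kernels: tuple = (5, 3, 2)
    dense_units: tuple = (512, 256, 128, 64)
    dropout_rate: float = 0.6
    optimizer: str = "nadam"
    learning_rate: float = 1e-5
    batch_size: int = 4
    epochs: int = 2000
    loss: str = "categorical_crossentropy"
    val_fraction: float = 0.15
    split_strategy: str = "per_spectrum"
    seed: int = 0
    best_checkpoint: bool = False  # keep last-epoch weights by default

    def __post_init__(self):
        object.__setattr__(self, "conv_filters", tuple(self.conv_filters))
        object.__setattr__(self, "conv_kernels", tuple(self.conv_kernels))
        object.__setattr__(self, "dense_units", tuple(self.dense_units))
        if len(self.conv_filters) != len(self.conv_kernels):
            raise ConfigurationError("conv_filters and conv_kernels must align")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout rate must be in [0, 1)")
        if not 0 < self.val_fraction < 1:
            raise ConfigurationError("val_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch size must be >= 1")
        if self.optimizer != "nadam":
            raise ConfigurationError("only the nadam optimizer is supported")
        if self.loss != "categorical_crossentropy":
            raise ConfigurationError("only categorical crossentropy is supported")
        if self.split_strategy not in ("per_spectrum", "per_sample"):
            raise ConfigurationError(
                "split_strategy must be 'per_spectrum' or 'per_sample'"
            )


#: Epoch budget used for the smaller repeated-samples protocol.
REPEATS_EPOCHS = 1500


@dataclass
class TrainingHistory:
    """Per-epoch curves; accuracies are percentages in [0, 100]."""

    train_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)

    def __len__(self):
        return len(self.train_loss)

    def append_epoch(self, tl, ta, vl, va):
        self.train_loss.append(float(tl))
        self.train_accuracy.append(float(ta))
        self.val_loss.append(float(vl))
        self.val_accuracy.append(float(va))

    def to_dict(self):
        return asdict(self)


def split(dataset: LabeledDataset, val_fraction: float = 0.15,
          strategy: str = "per_spectrum", seed: int = 0
          ) -> tuple[LabeledDataset, LabeledDataset]:
    """Randomly mask a validation fraction of the data.

    ``per_spectrum`` masks ``ceil(val_fraction * n)`` scans uniformly without
    replacement — the protocol under which replicate scans of one physical
    sample land on both sides of the split.  ``per_sample`` assigns whole
    sample groups to validation until the fraction is reached, so no group
    straddles the split.
    """
    n = len(dataset)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5717)))
    labels = dataset.labels

    if strategy == "per_spectrum":
        for cls in dataset.vocabulary:
            if (labels == cls).sum() < 2:
                raise StratificationError(
                    f"class {cls!r} has fewer than 2 spectra; cannot split"
                )
        n_val = int(np.ceil(val_fraction * n))
        val_rows = rng.choice(n, size=n_val, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[val_rows] = True
    elif strategy == "per_sample":
        groups = dataset.groups
        for cls in dataset.vocabulary:
            if len(set(groups[labels == cls].tolist())) < 2:
                raise StratificationError(
                    f"class {cls!r} has fewer than 2 sample groups; cannot "
                    "split per sample"
                )
        uniq = sorted(set(groups.tolist()))
        order = rng.permutation(len(uniq))
        mask = np.zeros(n, dtype=bool)
        n_val = 0
        for gi in order:
            if n_val >= val_fraction * n:
                break
            sel = groups == uniq[gi]
            mask |= sel
            n_val += int(sel.sum())
        missing = [c for c in dataset.vocabulary if not np.any(labels[~mask] == c)]
        if missing:
            raise StratificationError(
                f"per-sample split left no training groups for classes {missing}"
            )
    else:
        raise ConfigurationError(f"unknown split strategy {strategy!r}")

    return dataset.subset(np.flatnonzero(~mask)), dataset.subset(np.flatnonzero(mask))


class WoodClassifier:
    """A (possibly trained) spectral classifier with its input contract."""

    def __init__(self, net: nn.Network, vocabulary: list[str], grid: FeatureGrid,
                 config: CNNConfig, history: TrainingHistory | None = None):
        self.net = net
        self.vocabulary = list(vocabulary)
        self.grid = grid
        self.config = config
        self.history = history or TrainingHistory()

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def _check_features(self, features) -> np.ndarray:
        if isinstance(features, LabeledDataset):
            if features.grid != self.grid:
                raise GridMismatchError(
                    f"dataset grid {features.grid} != training grid {self.grid}"
                )
            features = features.features
        x = np.asarray(features, dtype=np.float32)
        if x.ndim == 1:
            x = x[None, :]
        if x.ndim != 2 or x.shape[1] != self.grid.n_bins:
            raise GridMismatchError(
                f"features have width {x.shape[-1]}, classifier expects "
                f"{self.grid.n_bins} bins on {self.grid}"
            )
        return x

    def predict_proba(self, features) -> np.ndarray:
        """Class-probability rows (softmax output) in vocabulary order."""
        x = self._check_features(features)
        logits = self.net.forward(x[:, :, None], training=False)
        return nn.softmax(logits)

    def predict(self, features) -> np.ndarray:
        """Predicted species labels (argmax of the probability rows)."""
        idx = self.predict_proba(features).argmax(axis=1)
        return np.array([self.vocabulary[i] for i in idx])


def build(config: CNNConfig, n_bins: int, n_classes: int,
          grid: FeatureGrid | None = None,
          vocabulary: list[str] | None = None) -> WoodClassifier:
    """Assemble the untrained network for a given input width and class count."""
    if n_classes < 2:
        raise ArchitectureError("need at least two classes")
    if grid is None:
        grid = FeatureGrid(0.0, n_bins * 0.1, 0.1)
    if grid.n_bins != n_bins:
        raise ConfigurationError("grid does not match n_bins")
    if vocabulary is None:
        vocabulary = [f"class_{i}" for i in range(n_classes)]
    if len(vocabulary) != n_classes:
        raise ConfigurationError("vocabulary size does not match n_classes")

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x1417)))
    layers: list[nn.Layer] = []
    shape = (1, n_bins, 1)
    try:
        c_in = 1
        for filters, kernel in zip(config.conv_filters, config.conv_kernels):
            conv = nn.Conv1D(c_in, filters, kernel, rng)
            shape = conv.out_shape(shape)
            pool = nn.MaxPool1D(2)
            layers += [conv, nn.BatchNorm(filters), nn.ReLU(), pool]
            shape = pool.out_shape(shape)
            c_in = filters
        flat = nn.Flatten()
        layers.append(flat)
        shape = flat.out_shape(shape)
        width = shape[1]
        for units in config.dense_units:
            layers += [nn.Dense(width, units, rng), nn.ReLU(),
                       nn.Dropout(config.dropout_rate)]
            width = units
        layers.append(nn.Dense(width, n_classes, rng))
    except ValueError as exc:
        raise ArchitectureError(
            f"input of {n_bins} bins cannot pass through the conv/pool stack: {exc}"
        ) from exc
    return WoodClassifier(nn.Network(layers), vocabulary, grid, config)


def _onehot(indices: np.ndarray, k: int) -> np.ndarray:
    return np.eye(k, dtype=np.float32)[indices]


def _eval_loss_acc(classifier: WoodClassifier, x3: np.ndarray, y_idx: np.ndarray,
                   chunk: int = 256) -> tuple[float, float]:
    k = len(classifier.vocabulary)
    losses, hits, n = 0.0, 0, len(x3)
    for s in range(0, n, chunk):
        logits = classifier.net.forward(x3[s : s + chunk], training=False)
        loss, _ = nn.softmax_crossentropy(logits, _onehot(y_idx[s : s + chunk], k))
        losses += loss * len(logits)
        hits += int((logits.argmax(axis=1) == y_idx[s : s + chunk]).sum())
    return losses / n, 100.0 * hits / n


def train(classifier: WoodClassifier, train_set: LabeledDataset,
          val_set: LabeledDataset, config: CNNConfig | None = None
          ) -> tuple[WoodClassifier, TrainingHistory]:
    """Run exactly ``config.epochs`` epochs of Nadam mini-batch training.

    No early stopping and no learning-rate schedule; the returned model is
    the last-epoch model (or the best-validation checkpoint when
    ``config.best_checkpoint`` is set).  The history records every epoch and
    appends when a loaded model is retrained.
    """
    if config is None:
        config = classifier.config
    for ds in (train_set, val_set):
        if ds.grid != classifier.grid:
            raise GridMismatchError("train/validation grid differs from model grid")
        if set(ds.vocabulary) - set(classifier.vocabulary):
            raise ConfigurationError("dataset vocabulary exceeds model vocabulary")
    lut = {lab: i for i, lab in enumerate(classifier.vocabulary)}
    ytr = np.array([lut[l] for l in train_set.labels.tolist()])
    yva = np.array([lut[l] for l in val_set.labels.tolist()])
    present = np.unique(ytr)
    empty = [classifier.vocabulary[i] for i in range(len(classifier.vocabulary))
             if i not in set(present.tolist())]
    if empty:
        raise ConfigurationError(f"classes with no training rows: {empty}")

    xtr = train_set.features[:, :, None].astype(np.float32)
    xva = val_set.features[:, :, None].astype(np.float32)
    k = len(classifier.vocabulary)
    onehot_tr = _onehot(ytr, k)

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x7123)))
    opt = nn.Nadam(lr=config.learning_rate)
    history = classifier.history
    best_va, best_state = -1.0, None

    for _epoch in range(config.epochs):
        order = rng.permutation(len(xtr))
        ep_loss, ep_hits = 0.0, 0
        for s in range(0, len(order), config.batch_size):
            idx = order[s : s + config.batch_size]
            logits = classifier.net.forward(xtr[idx], training=True, rng=rng)
            loss, dlogits = nn.softmax_crossentropy(logits, onehot_tr[idx])
            classifier.net.backward(dlogits)
            opt.step(classifier.net.params())
            ep_loss += loss * len(idx)
            ep_hits += int((logits.argmax(axis=1) == ytr[idx]).sum())
        vl, va = _eval_loss_acc(classifier, xva, yva)
        history.append_epoch(ep_loss / len(xtr), 100.0 * ep_hits / len(xtr), vl, va)
        if config.best_checkpoint and va > best_va:
            best_va = va
            best_state = {key: arr.copy() for key, arr in
                          classifier.net.state_arrays().items()}

    if config.best_checkpoint and best_state is not None:
        classifier.net.load_state(best_state)
    classifier.config = config
    return classifier, history


def save(classifier: WoodClassifier, path: str | Path) -> Path:
    """Persist a model as a directory: opaque weights + plain-text sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz", **classifier.net.state_arrays())
    meta = {
        "vocabulary": classifier.vocabulary,
        "grid": classifier.grid.to_dict(),
        "config": asdict(classifier.config),
        "history": classifier.history.to_dict(),
        "n_parameters": classifier.n_parameters,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    (path / "model.json").write_text(json.dumps(meta, indent=2))
    return path


def load(path: str | Path) -> WoodClassifier:
    """Rebuild a saved model; predictions are bit-identical to pre-save."""
    path = Path(path)
    meta_path = path / "model.json"
    weights_path = path / "weights.npz"
    if not meta_path.exists() or not weights_path.exists():
        raise IntegrityError(f"model artifact at {path} is incomplete")
    meta = json.loads(meta_path.read_text())
    for key in ("vocabulary", "grid", "config"):
        if key not in meta:
            raise IntegrityError(f"model sidecar missing {key!r}")
    config = CNNConfig(**meta["config"])
    grid = FeatureGrid(**meta["grid"])
    classifier = build(config, grid.n_bins, len(meta["vocabulary"]), grid=grid,
                       vocabulary=meta["vocabulary"])
    with np.load(weights_path) as arrays:
        try:
            classifier.net.load_state(dict(arrays))
        except (KeyError, ValueError) as exc:
            raise IntegrityError(f"corrupt weights in {weights_path}: {exc}") from exc
    hist = meta.get("history", {})
    classifier.history = TrainingHistory(**hist) if hist else TrainingHistory()
    return classifier
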