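"""Parallel Convolutional Spatiotemporal Network for posture classification.

The network reads a posture window (T time steps x 24 accelerometer
channels) through two parallel paths:

* a spatial path of three parallel convolutional blocks.  Each block stacks
  two temporal convolutions with ReLU (the blocks differ by kernel size:
  3, 5 and 7 samples) and summarizes its feature sequence with global max
  pooling and global average pooling side by side;
* a temporal path of one unidirectional LSTM and one bidirectional LSTM,
  each contributing its final hidden state (both directions for the
  Bi-LSTM).

The five branch outputs are concatenated along the feature dimension and a
single fully connected layer with softmax produces the six posture
probabilities.  Ablation variants built from the same blocks (CNN only,
serial CNN->LSTM, serial CNN->Bi-LSTM) are provided for comparison.

Training minimizes softmax cross-entropy with Adam (defaults: learning rate
1e-4, batch size 64, hidden size 10); runs are bitwise-repeatable for a
fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import _nn
from .synthetic_data import PostureDataset

__all__ = [
    "CNNBlockSpec",
    "PCSNConfig",
    "TrainedModel",
    "ClassificationReport",
    "build_model",
    "baseline_models",
    "split_dataset",
    "train",
    "evaluate",
    "classification_report_from_confusion",
    "cluster_consistency_filter",
    "grid_search",
    "save_checkpoint",
    "load_checkpoint",
]

BASELINE_NAMES = ("cnn", "cnn_lstm", "cnn_bilstm", "pcsn")


@dataclass(frozen=True)
class CNNBlockSpec:
    kernel: int = 3
    channels: tuple[int, int] = (32, 64)


@dataclass(frozen=True)
class PCSNConfig:
    """Architecture and training hyperparameters."""

    optimizer_name: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 64
    hidden_size: int = 10
    max_epochs: int = 400
    n_classes: int = 6
    n_channels: int = 24
    cnn_block_specs: tuple[CNNBlockSpec, ...] = (
        CNNBlockSpec(kernel=3),
        CNNBlockSpec(kernel=5),
        CNNBlockSpec(kernel=7),
    )
    seed: int = 0


# ---------------------------------------------------------------------------
# network definitions


class _ConvStack:
    """Two temporal convolutions with ReLU, preserving the time axis."""

    def __init__(self, c_in: int, spec: CNNBlockSpec, rng):
        c1, c2 = spec.channels
        self.layers = [
            _nn.Conv1d(c_in, c1, spec.kernel, rng),
            _nn.ReLU(),
            _nn.Conv1d(c1, c2, spec.kernel, rng),
            _nn.ReLU(),
        ]
        self.out_channels = c2

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def gradients(self):
        return [p for l in self.layers for p in l.gradients()]


class _PooledConvBlock:
    """Conv stack followed by parallel global max and average pooling."""

    def __init__(self, c_in: int, spec: CNNBlockSpec, rng):
        self.stack = _ConvStack(c_in, spec, rng)
        self.maxpool = _nn.GlobalMaxPool1d()
        self.avgpool = _nn.GlobalAvgPool1d()
        self.out_dim = 2 * self.stack.out_channels

    def forward(self, x):
        h = self.stack.forward(x)
        return np.concatenate(
            [self.maxpool.forward(h), self.avgpool.forward(h)], axis=1
        )

    def backward(self, g):
        c = self.stack.out_channels
        dh = self.maxpool.backward(g[:, :c]) + self.avgpool.backward(g[:, c:])
        return self.stack.backward(dh)

    def parameters(self):
        return self.stack.parameters()

    def gradients(self):
        return self.stack.gradients()


class _BaseNet:
    """Shared prediction surface of all network variants."""

    config: PCSNConfig

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[np.ndarray]:
        raise NotImplementedError

    def gradients(self) -> list[np.ndarray]:
        raise NotImplementedError

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _nn.softmax(self.forward(np.asarray(x, dtype=float)))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


class PCSNNet(_BaseNet):
    """The parallel spatial (CNN) + temporal (LSTM/Bi-LSTM) network."""

    kind = "pcsn"

    def __init__(self, config: PCSNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        C = config.n_channels
        self.blocks = [
            _PooledConvBlock(C, spec, rng) for spec in config.cnn_block_specs
        ]
        self.lstm = _nn.LSTM(C, config.hidden_size, rng)
        self.bilstm = _nn.BiLSTM(C, config.hidden_size, rng)
        self.branch_dims = [b.out_dim for b in self.blocks] + [
            config.hidden_size,
            2 * config.hidden_size,
        ]
        self.fused_dim = sum(self.branch_dims)
        self.fc = _nn.Dense(self.fused_dim, config.n_classes, rng)

    def forward(self, x):
        feats = [b.forward(x) for b in self.blocks]
        feats.append(self.lstm.forward(x))
        feats.append(self.bilstm.forward(x))
        return self.fc.forward(np.concatenate(feats, axis=1))

    def backward(self, g):
        dfused = self.fc.backward(g)
        pieces = np.split(dfused, np.cumsum(self.branch_dims)[:-1], axis=1)
        dx = self.blocks[0].backward(pieces[0])
        for blk, piece in zip(self.blocks[1:], pieces[1 : len(self.blocks)]):
            dx = dx + blk.backward(piece)
        dx = dx + self.lstm.backward(pieces[-2])
        dx = dx + self.bilstm.backward(pieces[-1])
        return dx

    def parameters(self):
        out = [p for b in self.blocks for p in b.parameters()]
        return out + self.lstm.parameters() + self.bilstm.parameters() + self.fc.parameters()

    def gradients(self):
        out = [p for b in self.blocks for p in b.gradients()]
        return out + self.lstm.gradients() + self.bilstm.gradients() + self.fc.gradients()


class CNNNet(_BaseNet):
    """Spatial path only: the three parallel convolutional blocks."""

    kind = "cnn"

    def __init__(self, config: PCSNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        C = config.n_channels
        self.blocks = [
            _PooledConvBlock(C, spec, rng) for spec in config.cnn_block_specs
        ]
        self.branch_dims = [b.out_dim for b in self.blocks]
        self.fused_dim = sum(self.branch_dims)
        self.fc = _nn.Dense(self.fused_dim, config.n_classes, rng)

    def forward(self, x):
        feats = [b.forward(x) for b in self.blocks]
        return self.fc.forward(np.concatenate(feats, axis=1))

    def backward(self, g):
        dfused = self.fc.backward(g)
        pieces = np.split(dfused, np.cumsum(self.branch_dims)[:-1], axis=1)
        dx = self.blocks[0].backward(pieces[0])
        for blk, piece in zip(self.blocks[1:], pieces[1:]):
            dx = dx + blk.backward(piece)
        return dx

    def parameters(self):
        return [p for b in self.blocks for p in b.parameters()] + self.fc.parameters()

    def gradients(self):
        return [p for b in self.blocks for p in b.gradients()] + self.fc.gradients()


class _SerialConvRecurrentNet(_BaseNet):
    """Serial CNN -> recurrent baseline: conv stack feeds the recurrent cell."""

    def __init__(self, config: PCSNConfig, bidirectional: bool):
        self.config = config
        rng = np.random.default_rng(config.seed)
        spec = config.cnn_block_specs[0]
        self.stack = _ConvStack(config.n_channels, spec, rng)
        if bidirectional:
            self.rnn = _nn.BiLSTM(self.stack.out_channels, config.hidden_size, rng)
            rnn_dim = 2 * config.hidden_size
        else:
            self.rnn = _nn.LSTM(self.stack.out_channels, config.hidden_size, rng)
            rnn_dim = config.hidden_size
        self.fc = _nn.Dense(rnn_dim, config.n_classes, rng)

    def forward(self, x):
        return self.fc.forward(self.rnn.forward(self.stack.forward(x)))

    def backward(self, g):
        return self.stack.backward(self.rnn.backward(self.fc.backward(g)))

    def parameters(self):
        return self.stack.parameters() + self.rnn.parameters() + self.fc.parameters()

    def gradients(self):
        return self.stack.gradients() + self.rnn.gradients() + self.fc.gradients()


class CNNLSTMNet(_SerialConvRecurrentNet):
    kind = "cnn_lstm"

    def __init__(self, config: PCSNConfig):
        super().__init__(config, bidirectional=False)


class CNNBiLSTMNet(_SerialConvRecurrentNet):
    kind = "cnn_bilstm"

    def __init__(self, config: PCSNConfig):
        super().__init__(config, bidirectional=True)


def build_model(config: PCSNConfig = PCSNConfig()) -> PCSNNet:
    """Untrained PCSN with parameters initialized from config.seed."""
    return PCSNNet(config)


def baseline_models(name: str, config: PCSNConfig = PCSNConfig()) -> _BaseNet:
    """Ablation variants sharing the PCSN building blocks."""
    table = {
        "cnn": CNNNet,
        "cnn_lstm": CNNLSTMNet,
        "cnn_bilstm": CNNBiLSTMNet,
        "pcsn": PCSNNet,
    }
    if name not in table:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(table)}")
    return table[name](config)


# ---------------------------------------------------------------------------
# dataset split


def split_dataset(
    dataset: PostureDataset,
    fraction: float = 2.0 / 3.0,
    seed: int = 0,
    by_subject: bool = False,
) -> tuple[PostureDataset, PostureDataset]:
    """Random stratified train/test split at the given training fraction.

    Stratification is per class (each class contributes round(fraction *
    class size) training windows).  ``by_subject=True`` instead holds out
    whole subjects, a stricter protocol for testing cross-subject
    generalization.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie strictly in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    if by_subject:
        subs = np.unique(dataset.subjects)
        n_train = int(round(fraction * subs.size))
        if n_train == 0 or n_train == subs.size:
            raise ValueError("split leaves an empty train or test set")
        chosen = rng.permutation(subs)[:n_train]
        mask = np.isin(dataset.subjects, chosen)
        return dataset.subset(np.flatnonzero(mask)), dataset.subset(
            np.flatnonzero(~mask)
        )
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in np.unique(dataset.labels):
        idx = np.flatnonzero(dataset.labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 windows")
        idx = rng.permutation(idx)
        n_train = int(round(fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return dataset.subset(tr), dataset.subset(te)


# ---------------------------------------------------------------------------
# training and evaluation


@dataclass
class TrainedModel:
    """A fitted network plus its config and per-epoch history."""

    net: _BaseNet
    config: PCSNConfig
    history: dict[str, list[float]] = field(default_factory=dict)

    def predict_proba(self, x):
        return self.net.predict_proba(x)

    def predict(self, x):
        return self.net.predict(x)


def _make_optimizer(net: _BaseNet, config: PCSNConfig):
    name = config.optimizer_name.lower()
    if name == "adam":
        return _nn.Adam(net.parameters(), net.gradients(), lr=config.learning_rate)
    if name == "sgd":
        return _nn.SGD(net.parameters(), net.gradients(), lr=config.learning_rate)
    raise ValueError(f"unknown optimizer {config.optimizer_name!r}")


def _batched_eval(net: _BaseNet, X, y, batch_size: int) -> tuple[float, float]:
    """(mean cross-entropy, accuracy) without building one huge activation."""
    n = len(y)
    loss_sum = 0.0
    correct = 0
    for start in range(0, n, batch_size):
        xb = X[start : start + batch_size]
        yb = y[start : start + batch_size]
        logits = net.forward(xb)
        loss, _ = _nn.cross_entropy(logits, yb)
        loss_sum += loss * len(yb)
        correct += int((logits.argmax(axis=1) == yb).sum())
    return loss_sum / n, correct / n


def train(
    net: _BaseNet,
    train_set: PostureDataset,
    test_set: PostureDataset | None = None,
    config: PCSNConfig | None = None,
    epochs: int | None = None,
    log=None,
) -> TrainedModel:
    """Fit a network by mini-batch cross-entropy descent; record history.

    Batch order is drawn from config.seed, so a run is exactly repeatable.
    ``epochs`` overrides config.max_epochs.  ``log`` is an optional callable
    receiving one dict per epoch.
    """
    if config is None:
        config = net.config
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    n_epochs = config.max_epochs if epochs is None else epochs
    X = np.asarray(train_set.signals, dtype=float)
    y = np.asarray(train_set.labels, dtype=np.intp)
    opt = _make_optimizer(net, config)
    rng = np.random.default_rng(config.seed + 1)
    history: dict[str, list[float]] = {
        "epoch": [],
        "train_loss": [],
        "train_acc": [],
        "test_loss": [],
        "test_acc": [],
    }
    for epoch in range(1, n_epochs + 1):
        order = rng.permutation(len(y))
        loss_sum = 0.0
        correct = 0
        for start in range(0, len(y), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = net.forward(X[idx])
            loss, dlogits = _nn.cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch} "
                    f"(lr={config.learning_rate}, optimizer="
                    f"{config.optimizer_name})"
                )
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            loss_sum += loss * idx.size
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        history["epoch"].append(epoch)
        history["train_loss"].append(loss_sum / len(y))
        history["train_acc"].append(correct / len(y))
        if test_set is not None and len(test_set):
            te_loss, te_acc = _batched_eval(
                net,
                np.asarray(test_set.signals, dtype=float),
                np.asarray(test_set.labels, dtype=np.intp),
                config.batch_size,
            )
        else:
            te_loss, te_acc = float("nan"), float("nan")
        history["test_loss"].append(te_loss)
        history["test_acc"].append(te_acc)
        if log is not None:
            log({k: v[-1] for k, v in history.items()})
    return TrainedModel(net=net, config=config, history=history)


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion matrix and macro-averaged scalar metrics."""

    confusion: np.ndarray
    accuracy: float
    precision: float
    recall: float
    f1: float

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def classification_report_from_confusion(confusion: np.ndarray) -> ClassificationReport:
    """Macro accuracy/precision/recall/F1 from a square confusion matrix.

    Rows are true classes, columns predictions.  Per-class ratios with an
    empty denominator (a class never predicted / never present) count as 0
    in the macro average.
    """
    confusion = np.asarray(confusion, dtype=np.int64)
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(confusion).astype(float)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    return ClassificationReport(
        confusion=confusion,
        accuracy=float(tp.sum() / total),
        precision=float(prec.mean()),
        recall=float(rec.mean()),
        f1=float(f1.mean()),
    )


def evaluate(model: TrainedModel | _BaseNet, test_set: PostureDataset) -> ClassificationReport:
    """Confusion matrix and macro metrics of a model on a labeled set."""
    if len(test_set) == 0:
        raise ValueError("evaluation set is empty")
    net = model.net if isinstance(model, TrainedModel) else model
    n_classes = net.config.n_classes
    y = np.asarray(test_set.labels, dtype=np.intp)
    pred = np.concatenate(
        [
            net.predict(test_set.signals[s : s + 256])
            for s in range(0, len(test_set), 256)
        ]
    )
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(confusion, (y, pred), 1)
    return classification_report_from_confusion(confusion)


# ---------------------------------------------------------------------------
# optional clustering/classification bridge and grid search


def cluster_consistency_filter(
    dataset: PostureDataset, cluster_labels: np.ndarray
) -> np.ndarray:
    """Indices of windows whose cluster agrees with their posture label.

    Each cluster is mapped to its majority posture label; windows whose
    cluster majority differs from their own label are flagged as
    inconsistent and dropped.  This is one documented way an unsupervised
    pre-clustering pass can clean a labeled training set before classifier
    training.
    """
    cluster_labels = np.asarray(cluster_labels)
    if cluster_labels.size != len(dataset):
        raise ValueError("cluster label vector does not match the dataset")
    keep = np.zeros(len(dataset), dtype=bool)
    for c in np.unique(cluster_labels):
        members = np.flatnonzero(cluster_labels == c)
        values, counts = np.unique(dataset.labels[members], return_counts=True)
        majority = values[counts.argmax()]
        keep[members[dataset.labels[members] == majority]] = True
    return np.flatnonzero(keep)


def grid_search(
    param_grid: dict[str, list],
    train_set: PostureDataset,
    val_set: PostureDataset,
    base_config: PCSNConfig = PCSNConfig(),
    epochs: int = 20,
    model_name: str = "pcsn",
) -> tuple[PCSNConfig, list[dict]]:
    """Exhaustive search over user-specified hyperparameter ranges.

    Returns the best config (by validation accuracy) and the full trial log.
    """
    from itertools import product

    keys = list(param_grid)
    results = []
    best = (None, -1.0)
    for combo in product(*(param_grid[k] for k in keys)):
        cfg = replace(base_config, **dict(zip(keys, combo)))
        net = baseline_models(model_name, cfg)
        fitted = train(net, train_set, val_set, cfg, epochs=epochs)
        acc = fitted.history["test_acc"][-1]
        results.append({**dict(zip(keys, combo)), "val_acc": acc})
        if acc > best[1]:
            best = (cfg, acc)
    return best[0], results


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: TrainedModel, path) -> None:
    """Single-file archive: weights plus embedded JSON config and history."""
    cfg = asdict(model.config)
    cfg["cnn_block_specs"] = [
        {"kernel": s.kernel, "channels": list(s.channels)}
        for s in model.config.cnn_block_specs
    ]
    meta = json.dumps(
        {"kind": model.net.kind, "config": cfg, "history": model.history}
    )
    arrays = {f"param_{i}": p for i, p in enumerate(model.net.parameters())}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_d = meta["config"]
        cfg_d["cnn_block_specs"] = tuple(
            CNNBlockSpec(kernel=s["kernel"], channels=tuple(s["channels"]))
            for s in cfg_d["cnn_block_specs"]
        )
        config = PCSNConfig(**cfg_d)
        net = baseline_models(meta["kind"], config)
        for i, p in enumerate(net.parameters()):
            p[...] = data[f"param_{i}"]
    return TrainedModel(net=net, config=config, history=meta["history"])
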