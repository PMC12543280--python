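"""1-D CNN trace classifiers and their training protocol.

Two classifiers are trained: a 2-class model for green traces (rejected /
1-step) and a 4-class model for far-red traces (rejected / 1-step / 2-step /
3-and-higher-step).  The protocol: inverse class frequency weighting of the
loss, a stratified randomized 80/20 train-validation split, an architecture
search ranked by validation accuracy whose top five candidates are re-scored
by stratified 5-fold cross-validation (mean accuracy and F1 across folds),
and final training on 100% of the labeled data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .nn import Conv1DNet, weighted_cross_entropy, softmax
from .stepcount import FARRED_CLASSES, GREEN_CLASSES

__all__ = [
    "ArchitectureSpec",
    "TrainingConfig",
    "LabeledDataset",
    "TrainedClassifier",
    "TrainingError",
    "compute_class_weights",
    "stratified_split",
    "train",
    "cross_validate",
    "search",
    "default_search_grid",
    "classify",
    "confusion_matrix",
]


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative 1-D CNN architecture.

    ``conv_blocks`` is a list of ``(kernel_size, n_filters)``; each block is
    conv -> ReLU -> max pool.  ``head_bins`` sets the coarse time resolution
    of the average-pooling head feeding the dense stack.
    """

    conv_blocks: tuple[tuple[int, int], ...]
    dense: tuple[int, ...]
    n_classes: int
    pool_size: int = 4
    head_bins: int = 32

    def __post_init__(self) -> None:
        if len(self.conv_blocks) < 1:
            raise ValueError("need at least one conv block")
        if self.n_classes not in (2, 4):
            raise ValueError("n_classes must be 2 (green) or 4 (far-red)")

    def build(self, input_length: int, rng: np.random.Generator) -> Conv1DNet:
        return Conv1DNet(
            input_length,
            [tuple(cb) for cb in self.conv_blocks],
            list(self.dense),
            self.n_classes,
            self.pool_size,
            self.head_bins,
            rng,
        )

    def to_dict(self) -> dict:
        return {
            "conv_blocks": [list(cb) for cb in self.conv_blocks],
            "dense": list(self.dense),
            "n_classes": self.n_classes,
            "pool_size": self.pool_size,
            "head_bins": self.head_bins,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(
            conv_blocks=tuple(tuple(cb) for cb in d["conv_blocks"]),
            dense=tuple(d["dense"]),
            n_classes=int(d["n_classes"]),
            pool_size=int(d.get("pool_size", 4)),
            head_bins=int(d.get("head_bins", 32)),
        )


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 8
    seed: int = 0
    split_fraction: float = 0.8
    class_weights: np.ndarray | None = None
    k_folds: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


def _classes_for(channel: str) -> tuple[str, ...]:
    if channel == "farred":
        return tuple(FARRED_CLASSES)
    if channel == "green":
        return tuple(GREEN_CLASSES)
    raise ValueError(f"unknown channel: {channel!r}")


@dataclass
class LabeledDataset:
    """Z-scored traces with integer class labels and replicate metadata."""

    X: np.ndarray  # (n, L) float32, Z-scored
    y: np.ndarray  # (n,) int class indices
    class_names: tuple[str, ...]
    channel: str
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be (n, L) with one label per row")
        if self.y.size and (self.y.min() < 0 or self.y.max() >= len(self.class_names)):
            raise ValueError("label index outside class set")

    @classmethod
    def from_labels(
        cls, X: np.ndarray, labels: list[str], channel: str, meta: pd.DataFrame | None = None
    ) -> "LabeledDataset":
        names = _classes_for(channel)
        index = {c: i for i, c in enumerate(names)}
        try:
            y = np.array([index[l] for l in labels], dtype=int)
        except KeyError as exc:
            raise ValueError(f"label {exc} not in class set for channel {channel!r}") from exc
        return cls(X, y, names, channel, meta)

    def __len__(self) -> int:
        return len(self.y)

    @property
    def input_length(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.y, minlength=len(self.class_names))
        return {c: int(n) for c, n in zip(self.class_names, counts)}

    def labels(self) -> np.ndarray:
        return np.array([self.class_names[i] for i in self.y])

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        meta = self.meta.iloc[idx].reset_index(drop=True) if self.meta is not None else None
        return LabeledDataset(self.X[idx], self.y[idx], self.class_names, self.channel, meta)


def compute_class_weights(class_counts) -> np.ndarray:
    """Inverse class frequency weights w_c = N / (K * n_c).

    Underrepresented classes get larger weight; the weights satisfy
    sum_c w_c * n_c = N (mean weight 1 under the class distribution).
    Accepts a sequence of counts or a {class: count} mapping (insertion
    order).
    """
    if hasattr(class_counts, "values") and not isinstance(class_counts, np.ndarray):
        counts = np.array(list(class_counts.values()), dtype=float)
    else:
        counts = np.asarray(class_counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("all class counts must be > 0 for inverse-frequency weighting")
    N, K = counts.sum(), len(counts)
    return N / (K * counts)


def stratified_split(
    dataset: LabeledDataset, fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified randomized train/validation split preserving class proportions."""
    counts = np.bincount(dataset.y, minlength=len(dataset.class_names))
    present = counts[np.unique(dataset.y)]
    if np.any(present < 2):
        raise ValueError("every present class needs >= 2 members to stratify")
    idx = np.arange(len(dataset))
    tr, va = train_test_split(
        idx, train_size=fraction, stratify=dataset.y, random_state=seed, shuffle=True
    )
    return dataset.subset(np.sort(tr)), dataset.subset(np.sort(va))


@dataclass
class TrainedClassifier:
    """A trained CNN plus everything needed to reuse it."""

    arch: ArchitectureSpec
    net: Conv1DNet
    class_names: tuple[str, ...]
    input_length: int
    provenance: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.input_length:
            raise ValueError(f"traces must be (n, {self.input_length})")
        return self.net.predict_proba(X)

    def save(self, directory: str | Path) -> None:
        """Serialize as a directory: architecture JSON + class map + weights."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "architecture.json").write_text(json.dumps(self.arch.to_dict(), indent=2))
        (d / "class_map.json").write_text(
            json.dumps(
                {
                    "class_names": list(self.class_names),
                    "input_length": self.input_length,
                    "provenance": self.provenance,
                },
                indent=2,
            )
        )
        np.savez(d / "weights.npz", **self.net.state_dict())

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedClassifier":
        d = Path(directory)
        arch = ArchitectureSpec.from_dict(json.loads((d / "architecture.json").read_text()))
        m = json.loads((d / "class_map.json").read_text())
        net = arch.build(int(m["input_length"]), np.random.default_rng(0))
        with np.load(d / "weights.npz") as z:
            net.load_state_dict({k: z[k] for k in z.files})
        return cls(arch, net, tuple(m["class_names"]), int(m["input_length"]), m.get("provenance", {}))


def _config_hash(arch: ArchitectureSpec, config: TrainingConfig) -> str:
    payload = json.dumps(
        {
            "arch": arch.to_dict(),
            "lr": config.learning_rate,
            "batch": config.batch_size,
            "epochs": config.epochs,
            "seed": config.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _evaluate(net: Conv1DNet, ds: LabeledDataset, n_classes: int) -> dict:
    probs = net.predict_proba(ds.X)
    pred = probs.argmax(axis=1)
    acc = float((pred == ds.y).mean()) if len(ds) else float("nan")
    f1 = f1_score(ds.y, pred, labels=np.arange(n_classes), average=None, zero_division=0.0)
    return {
        "accuracy": acc,
        "per_class_f1": [float(v) for v in f1],
        "macro_f1": float(np.mean(f1)),
    }


def train(
    train_set: LabeledDataset,
    val_set: LabeledDataset | None,
    arch: ArchitectureSpec,
    config: TrainingConfig,
) -> tuple[TrainedClassifier, dict]:
    """Train one CNN with inverse-class-frequency-weighted cross entropy.

    Returns the trained classifier and validation metrics (accuracy and
    per-class F1; NaN accuracy when no validation set is supplied, as for
    final training on 100% of the data).  Deterministic given
    ``config.seed``.
    """
    if arch.n_classes != len(train_set.class_names):
        raise ValueError("architecture n_classes does not match dataset class set")
    rng = np.random.default_rng(config.seed)
    net = arch.build(train_set.input_length, rng)
    if config.class_weights is not None:
        weights = np.asarray(config.class_weights, dtype=float)
    else:
        counts = np.bincount(train_set.y, minlength=arch.n_classes).astype(float)
        # absent classes contribute no loss; guard the division
        weights = np.where(counts > 0, counts.sum() / (arch.n_classes * np.maximum(counts, 1)), 0.0)
    n = len(train_set)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits, cache = net.forward(train_set.X[idx], want_cache=True)
            probs = softmax(logits.astype(np.float64))
            loss, dlogits = weighted_cross_entropy(probs, train_set.y[idx], weights)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {_epoch}")
            grads = net.backward(dlogits.astype(np.float32), cache)
            net.adam_step(grads, config.learning_rate)
    metrics = (
        _evaluate(net, val_set, arch.n_classes)
        if val_set is not None and len(val_set)
        else {"accuracy": float("nan"), "per_class_f1": [], "macro_f1": float("nan")}
    )
    clf = TrainedClassifier(
        arch,
        net,
        train_set.class_names,
        train_set.input_length,
        provenance={"seed": config.seed, "config_hash": _config_hash(arch, config)},
    )
    return clf, metrics


def cross_validate(
    dataset: LabeledDataset,
    arch: ArchitectureSpec,
    config: TrainingConfig,
    k: int | None = None,
) -> dict:
    """Stratified k-fold cross-validation; per-fold accuracy/macro-F1 and mean +/- sd."""
    k = k or config.k_folds
    counts = np.bincount(dataset.y, minlength=len(dataset.class_names))
    smallest = counts[counts > 0].min()
    if k > smallest:
        raise ValueError(f"k={k} exceeds smallest class count {smallest}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    fold_metrics = []
    for tr_idx, va_idx in skf.split(dataset.X, dataset.y):
        _, m = train(dataset.subset(tr_idx), dataset.subset(va_idx), arch, config)
        fold_metrics.append(m)
    accs = np.array([m["accuracy"] for m in fold_metrics])
    f1s = np.array([m["macro_f1"] for m in fold_metrics])
    return {
        "folds": fold_metrics,
        "mean_accuracy": float(accs.mean()),
        "sd_accuracy": float(accs.std(ddof=1)),
        "mean_macro_f1": float(f1s.mean()),
        "sd_macro_f1": float(f1s.std(ddof=1)),
    }


def default_search_grid(n_classes: int) -> list[tuple[ArchitectureSpec, TrainingConfig]]:
    """Reduced default architecture grid: kernel x filters x dense stack."""
    out = []
    for kernel in (5, 15, 31):
        for filters in (8, 16):
            for dense in ((32,), (64, 32)):
                arch = ArchitectureSpec(
                    conv_blocks=((kernel, filters),), dense=dense, n_classes=n_classes
                )
                out.append((arch, TrainingConfig()))
    return out


def search(
    dataset: LabeledDataset,
    candidates: list[tuple[ArchitectureSpec, TrainingConfig]] | None = None,
    seed: int = 0,
    top_k: int = 5,
    cv_folds: int = 5,
) -> dict:
    """Architecture search following the two-stage selection protocol.

    Every candidate is trained on a stratified 80/20 split and ranked by
    validation accuracy; the top ``top_k`` are re-scored by stratified
    k-fold cross-validation, and the final pick maximizes CV mean accuracy
    (ties broken by mean macro-F1, then leaderboard order).  Deterministic
    given ``seed``.
    """
    if candidates is None:
        candidates = default_search_grid(len(dataset.class_names))
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    leaderboard = []
    for i, (arch, cfg) in enumerate(candidates):
        cfg_i = TrainingConfig(**{**asdict(cfg), "seed": seed, "class_weights": cfg.class_weights})
        tr, va = stratified_split(dataset, cfg_i.split_fraction, seed=seed)
        _, m = train(tr, va, arch, cfg_i)
        leaderboard.append(
            {
                "candidate": i,
                "arch": arch,
                "config": cfg_i,
                "val_accuracy": m["accuracy"],
                "val_macro_f1": m["macro_f1"],
            }
        )
    leaderboard.sort(key=lambda r: (-r["val_accuracy"], r["candidate"]))
    finalists = leaderboard[:top_k]
    for r in finalists:
        r["cv"] = cross_validate(dataset, r["arch"], r["config"], k=cv_folds)
    best = max(
        finalists,
        key=lambda r: (r["cv"]["mean_accuracy"], r["cv"]["mean_macro_f1"], -r["candidate"]),
    )
    return {"leaderboard": leaderboard, "finalists": finalists, "best": best}


def classify(
    model: TrainedClassifier, traces: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and per-class probabilities for Z-scored traces.

    ``traces`` is (n, L) with L equal to the model's input length; returns
    (labels as strings, probabilities (n, K) summing to 1 per row).
    """
    probs = model.predict_proba(traces)
    labels = np.array([model.class_names[i] for i in probs.argmax(axis=1)])
    return labels, probs


def confusion_matrix(
    y_true, y_pred, class_names: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Raw-count and row-normalized (recall) confusion matrices.

    Rows index the true class, columns the prediction; normalized rows sum
    to 1, or 0 for classes absent from ``y_true``.
    """
    index = {c: i for i, c in enumerate(class_names)}
    K = len(class_names)

    def encode(v):
        out = np.empty(len(v), dtype=int)
        for i, item in enumerate(v):
            if isinstance(item, (int, np.integer)):
                if not (0 <= item < K):
                    raise ValueError(f"label index {item} outside class set")
                out[i] = int(item)
            else:
                if item not in index:
                    raise ValueError(f"label {item!r} outside class set")
                out[i] = index[item]
        return out

    t, p = encode(list(y_true)), encode(list(y_pred))
    if len(t) != len(p):
        raise ValueError("label vectors must have equal length")
    raw = np.zeros((K, K), dtype=int)
    np.add.at(raw, (t, p), 1)
    row_sums = raw.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, raw / row_sums, 0.0)
    return raw, norm
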