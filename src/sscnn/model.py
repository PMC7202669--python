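"""The 4-layer window CNN: architecture, training protocol, cross-validation
splits, and majority-vote ensembling.

The predictor reads a (29, 92) feature window and returns a probability per
secondary-structure label for the central residue.  The reference
architecture is four valid-border convolutional layers of width 7 with 128,
256, 384 and 512 filters (ReLU), 30% dropout in front of every convolutional
layer and the final dense layer, and a softmax output.  With 29 input
positions the convolutional stack leaves 29 - 4*(7-1) = 5 positions, so the
dense layer sees 5 * 512 = 2560 features.

Training uses SGD (learning rate 0.01, momentum 0.9, no Nesterov) with
categorical cross-entropy, a decay constant of learning_rate / n_epochs, and
per-epoch checkpointing on validation accuracy: the model returned is the
one with the best validation accuracy seen at any epoch end, not the
last-epoch model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .features import N_FEATURES
from .labels import AlphabetScheme, get_scheme, reduce_alphabet

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "SampleSet",
    "TrainedModel",
    "EnsembleModel",
    "build_cnn",
    "parameter_count",
    "train",
    "make_cv_splits",
    "ensemble_predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyper-parameters of the window CNN."""

    n_labels: int = 8
    window_width: int = 29
    n_features: int = N_FEATURES
    kernel_width: int = 7
    filters: tuple = (128, 256, 384, 512)
    dropout_rate: float = 0.30

    def __post_init__(self) -> None:
        if self.n_labels < 2:
            raise ValueError(f"n_labels must be >= 2, got {self.n_labels}")
        if self.conv_output_length < 1:
            raise ValueError(
                f"window width {self.window_width} too small for "
                f"{len(self.filters)} layers of kernel width {self.kernel_width}"
            )

    @property
    def n_conv_layers(self) -> int:
        return len(self.filters)

    @property
    def conv_output_length(self) -> int:
        """Spatial length after the valid-border convolution stack."""
        return self.window_width - self.n_conv_layers * (self.kernel_width - 1)

    def to_dict(self) -> dict:
        return {
            "n_labels": self.n_labels,
            "window_width": self.window_width,
            "n_features": self.n_features,
            "kernel_width": self.kernel_width,
            "filters": list(self.filters),
            "dropout_rate": self.dropout_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["filters"] = tuple(d["filters"])
        return cls(**d)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyper-parameters; decay follows the learning rate and
    epoch count (``learning_rate / n_epochs``) unless set explicitly."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    nesterov: bool = False
    n_epochs: int = 650
    batch_size: int = 256
    seed: int = 0
    decay: float | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning rate and batch size must be positive")
        if self.n_epochs <= 0:
            raise ValueError("n_epochs must be positive")

    @property
    def effective_decay(self) -> float:
        return self.learning_rate / self.n_epochs if self.decay is None else self.decay


@dataclass
class SampleSet:
    """Featurized samples in one reduced alphabet.

    ``X`` has shape (n, window, 92); ``y`` holds integer label indices into
    ``letters``; ``chain_keys`` (optional) records each sample's chain.
    """

    X: np.ndarray
    y: np.ndarray
    letters: tuple
    chain_keys: list | None = None

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y lengths differ")
        if self.y.size and (self.y.min() < 0 or self.y.max() >= len(self.letters)):
            raise ValueError("label index outside alphabet")

    def __len__(self) -> int:
        return self.X.shape[0]

    @classmethod
    def from_windows(cls, samples: list, scheme: AlphabetScheme | str,
                     half_keys: bool = True) -> "SampleSet":
        """Build from (FeatureWindow, label8) pairs, reducing the labels."""
        if isinstance(scheme, str):
            scheme = get_scheme(scheme)
        letters = scheme.letters
        index = {l: i for i, l in enumerate(letters)}
        X = np.stack([w.matrix for w, _ in samples]).astype(np.float32)
        y = np.array([index[reduce_alphabet(l, scheme)] for _, l in samples],
                     dtype=np.int64)
        keys = [f"{w.pdb_id}:{w.chain_id}" for w, _ in samples] if half_keys else None
        return cls(X=X, y=y, letters=letters, chain_keys=keys)


def build_cnn(spec: ModelSpec, seed: int = 0) -> nn.Sequential:
    """Assemble the untrained CNN for ``spec`` with seeded initialization."""
    rng = np.random.default_rng(seed)
    layers: list = []
    in_ch = spec.n_features
    for out_ch in spec.filters:
        layers.append(nn.Dropout(spec.dropout_rate))
        layers.append(nn.Conv1D(in_ch, out_ch, spec.kernel_width, rng))
        layers.append(nn.ReLU())
        in_ch = out_ch
    layers.append(nn.Dropout(spec.dropout_rate))
    layers.append(nn.Flatten())
    layers.append(nn.Dense(spec.conv_output_length * in_ch, spec.n_labels, rng))
    return nn.Sequential(layers)


def parameter_count(spec: ModelSpec) -> int:
    """Trainable parameter count, in closed form.

    Each convolution contributes ``in_ch * k * out_ch + out_ch``; the dense
    layer contributes ``conv_output_length * last_filters * n_labels +
    n_labels``.
    """
    total = 0
    in_ch = spec.n_features
    for out_ch in spec.filters:
        total += in_ch * spec.kernel_width * out_ch + out_ch
        in_ch = out_ch
    total += spec.conv_output_length * in_ch * spec.n_labels + spec.n_labels
    return total


@dataclass
class TrainedModel:
    """A trained member: network, spec, alphabet, and training metadata."""

    network: nn.Sequential
    spec: ModelSpec
    letters: tuple
    best_valid_accuracy: float = float("nan")
    best_epoch: int = -1
    split_id: int = 0
    seed: int = 0

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(X.astype(np.float32))

    def predict(self, X: np.ndarray) -> str:
        idx = self.predict_proba(X).argmax(axis=1)
        return "".join(self.letters[i] for i in idx)


def train(
    network: nn.Sequential,
    train_set: SampleSet,
    valid_set: SampleSet,
    config: TrainConfig,
    spec: ModelSpec | None = None,
    split_id: int = 0,
) -> tuple:
    """Train with per-epoch validation checkpointing.

    Returns ``(TrainedModel, history)`` where ``history`` is a list of
    per-epoch dicts with train/validation accuracy and the learning rate.
    The returned model carries the weights of the epoch with the highest
    validation accuracy (ties keep the earlier epoch).  The train accuracy
    recorded per epoch is the running mean over that epoch's mini-batches
    (measured with dropout active).
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if train_set.letters != valid_set.letters:
        raise ValueError("train and validation sets use different alphabets")
    n_labels = len(train_set.letters)
    if train_set.y.max() >= n_labels:
        raise ValueError("label outside alphabet")

    rng = np.random.default_rng(config.seed)
    opt = nn.SGD(network.params, lr=config.learning_rate,
                 momentum=config.momentum, decay=config.effective_decay,
                 nesterov=config.nesterov)

    Xtr = train_set.X.astype(np.float32)
    ytr = train_set.y
    best_weights = network.get_weights()
    best_acc = -1.0
    best_epoch = -1
    history: list = []

    for epoch in range(config.n_epochs):
        order = rng.permutation(len(train_set))
        batch_accs = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            _, acc = network.loss_and_grad(Xtr[idx], ytr[idx], rng)
            opt.step(network.grads)
            batch_accs.append(acc)
        valid_pred = network.predict_proba(valid_set.X.astype(np.float32)).argmax(axis=1)
        valid_acc = float((valid_pred == valid_set.y).mean()) if len(valid_set) else float("nan")
        history.append({
            "epoch": epoch,
            "train_acc": float(np.mean(batch_accs)),
            "valid_acc": valid_acc,
            "lr": opt.current_lr,
        })
        if len(valid_set) and valid_acc > best_acc:
            best_acc = valid_acc
            best_epoch = epoch
            best_weights = network.get_weights()

    network.set_weights(best_weights)
    model = TrainedModel(
        network=network,
        spec=spec if spec is not None else ModelSpec(n_labels=n_labels),
        letters=train_set.letters,
        best_valid_accuracy=best_acc if best_epoch >= 0 else float("nan"),
        best_epoch=best_epoch,
        split_id=split_id,
        seed=config.seed,
    )
    return model, history


def make_cv_splits(chains: list, n_splits: int = 10, seed: int = 0) -> list:
    """Chain-level cross-validation partitions.

    The chains are shuffled once and divided into ``n_splits`` folds; split i
    uses fold i for validation and the rest for training, so with 10 splits
    every partition has a 9:1 chain-count ratio and every chain appears in
    exactly one validation fold.
    """
    chains = list(chains)
    if len(chains) < n_splits:
        raise ValueError(f"need at least {n_splits} chains, got {len(chains)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chains))
    folds = np.array_split(order, n_splits)
    splits = []
    for i, fold in enumerate(folds):
        valid = [chains[j] for j in fold]
        train_idx = np.concatenate([f for k, f in enumerate(folds) if k != i])
        splits.append(([chains[j] for j in train_idx], valid))
    return splits


@dataclass
class EnsembleModel:
    """An ensemble of independently trained members sharing one alphabet."""

    members: list
    scheme_name: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must have at least one member")
        letters = {m.letters for m in self.members}
        if len(letters) != 1:
            raise ValueError("ensemble members use different alphabets")

    @property
    def letters(self) -> tuple:
        return self.members[0].letters


def ensemble_predict(ensemble: EnsembleModel, windows: np.ndarray) -> tuple:
    """Majority-vote prediction over the ensemble members.

    Each member votes its argmax label per residue; the plurality label
    wins, with ties broken by the highest softmax probability summed across
    all members.  Returns ``(label_string, mean_probability_matrix)``.
    """
    letters = ensemble.letters
    n_labels = len(letters)
    probs = np.stack([m.predict_proba(windows) for m in ensemble.members])
    votes = probs.argmax(axis=2)  # (members, n)
    n = windows.shape[0]
    counts = np.zeros((n, n_labels), dtype=np.int64)
    for mem in votes:
        counts[np.arange(n), mem] += 1
    summed = probs.sum(axis=0)
    # plurality; break ties by summed probability over the tied labels only
    out = []
    for i in range(n):
        top = counts[i].max()
        tied = np.flatnonzero(counts[i] == top)
        if tied.size == 1:
            out.append(int(tied[0]))
        else:
            out.append(int(tied[np.argmax(summed[i, tied])]))
    label_string = "".join(letters[i] for i in out)
    return label_string, probs.mean(axis=0)


# ---------------------------------------------------------------------------
# Serialization: portable weights container with embedded spec + alphabet
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    weights = {f"w{i}": w for i, w in enumerate(model.network.get_weights())}
    np.savez(path / "weights.npz", **weights)
    meta = {
        "spec": model.spec.to_dict(),
        "letters": list(model.letters),
        "best_valid_accuracy": model.best_valid_accuracy,
        "best_epoch": model.best_epoch,
        "split_id": model.split_id,
        "seed": model.seed,
    }
    (path / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    spec = ModelSpec.from_dict(meta["spec"])
    network = build_cnn(spec, seed=meta.get("seed", 0))
    with np.load(path / "weights.npz") as data:
        weights = [data[f"w{i}"] for i in range(len(data.files))]
    network.set_weights(weights)
    return TrainedModel(
        network=network,
        spec=spec,
        letters=tuple(meta["letters"]),
        best_valid_accuracy=meta["best_valid_accuracy"],
        best_epoch=meta["best_epoch"],
        split_id=meta["split_id"],
        seed=meta.get("seed", 0),
    )
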