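"""End-to-end 3D CNN baseline classifier.

Thirteen layers: three {3x3x3 convolution -> stride-2 max-pool -> ReLU ->
batch-norm} feature blocks (that unconventional post-pool activation order
is the default, with a conventional-order switch), then flatten -> dense
256 -> 30% dropout -> dense 2 with sigmoid outputs trained by binary
cross-entropy on one-hot targets.  Evaluation follows the same stratified
80/20 hold-out + 5-fold cross-validation protocol as the tabular benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .core import ExperimentResult, Volume3D
from .nn import (
    Adam,
    BatchNorm,
    Conv3D,
    Dense,
    Dropout,
    Flatten,
    MaxPool3D,
    ReLU,
    Sequential,
    bce_with_logits,
    sigmoid,
)

DEFAULT_CROP = (22, 28, 40)


@dataclass
class CNNSpec:
    input_shape: tuple[int, int, int] = DEFAULT_CROP
    filters: tuple[int, int, int] = (32, 64, 64)
    dense_units: int = 256
    dropout_rate: float = 0.30
    conventional_order: bool = False  # True: conv -> BN -> ReLU -> pool
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 8
    seed: int = 0

    def feature_shape(self) -> tuple[int, ...]:
        cur = list(self.input_shape)
        for _ in range(3):
            for ax, n in enumerate(cur):
                half = n // 2
                if half < 1:
                    raise ValueError(
                        f"pooling collapses axis {ax} (size {self.input_shape[ax]}) below 1"
                    )
                cur[ax] = half
        return tuple(cur)

    @property
    def flat_dim(self) -> int:
        return int(np.prod(self.feature_shape())) * self.filters[-1]


def preprocess_for_cnn(volume: Volume3D, crop: tuple[int, int, int] = DEFAULT_CROP) -> np.ndarray:
    """Centre-crop to ``crop`` and min-max normalise to [0, 1].

    A constant crop maps to all zeros (degenerate-range rule).  Undersized
    axes are rejected by name.
    """
    data = np.asarray(volume.data, float)
    for ax, (n, c) in enumerate(zip(data.shape, crop)):
        if n < c:
            raise ValueError(f"axis {ax} of size {n} is smaller than crop size {c}")
    slices = tuple(
        slice((n - c) // 2, (n - c) // 2 + c) for n, c in zip(data.shape, crop)
    )
    out = data[slices]
    lo, hi = out.min(), out.max()
    if hi <= lo:
        return np.zeros(crop, np.float32)
    return ((out - lo) / (hi - lo)).astype(np.float32)


class CNN3D:
    """Model handle exposing the layer manifest, forward pass and training."""

    def __init__(self, spec: CNNSpec):
        spec.feature_shape()  # validates pooling
        rng = np.random.default_rng(spec.seed)
        f1, f2, f3 = spec.filters
        layers: list = []
        manifest: list[str] = []
        in_ch = 1
        for i, f in enumerate((f1, f2, f3), start=1):
            conv = Conv3D(in_ch, f, rng)
            if spec.conventional_order:
                block = [conv, BatchNorm(f), ReLU(), MaxPool3D()]
                names = [f"conv{i}", f"bn{i}", f"relu{i}", f"maxpool{i}"]
            else:
                block = [conv, MaxPool3D(), ReLU(), BatchNorm(f)]
                names = [f"conv{i}", f"maxpool{i}", f"relu{i}", f"bn{i}"]
            layers += block
            manifest += [n for n in names if not n.startswith("relu")]
            in_ch = f
        layers += [
            Flatten(),
            Dense(spec.flat_dim, spec.dense_units, rng),
            Dropout(spec.dropout_rate, np.random.default_rng(spec.seed + 7)),
            Dense(spec.dense_units, 2, rng),
        ]
        manifest += ["flatten", f"dense{spec.dense_units}",
                     f"dropout{spec.dropout_rate:.2f}", "dense2_sigmoid"]
        self.spec = spec
        self.model = Sequential(layers)
        self.layer_manifest = manifest  # 13 named layers

    def forward_proba(self, batch: np.ndarray) -> np.ndarray:
        return sigmoid(self.model.forward(batch, train=False))

    def predict(self, batch: np.ndarray) -> np.ndarray:
        return self.forward_proba(batch).argmax(axis=1)


def build_cnn(spec: CNNSpec | None = None) -> CNN3D:
    return CNN3D(spec or CNNSpec())


def train_cnn(model: CNN3D, X: np.ndarray, y: np.ndarray) -> list[float]:
    """Adam/BCE training on one-hot targets; one mean loss per epoch."""
    spec = model.spec
    targets = np.zeros((len(y), 2), np.float32)
    targets[np.arange(len(y)), y.astype(int)] = 1.0
    rng = np.random.default_rng(spec.seed + 3)
    opt = Adam(model.model, lr=spec.learning_rate)
    history = []
    for epoch in range(spec.epochs):
        order = rng.permutation(len(X))
        losses = []
        for s in range(0, len(X), spec.batch_size):
            idx = order[s : s + spec.batch_size]
            logits = model.model.forward(X[idx], train=True)
            loss, grad = bce_with_logits(logits, targets[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            model.model.backward(grad)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def train_eval_cnn(
    volumes: list,
    labels: np.ndarray,
    spec: CNNSpec | None = None,
    holdout_fraction: float = 0.20,
    cv_folds: int = 5,
    seed: int = 0,
) -> ExperimentResult:
    """Stratified 80/20 hold-out + k-fold CV evaluation of the CNN.

    Per fold a fresh model is trained on the fold's training portion,
    scored on the held fold, and additionally scored on the single
    hold-out set; means and stds are taken over the fold models.
    """
    spec = spec or CNNSpec()
    labels = np.asarray(labels, int)
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present")
    X = np.stack([
        v if isinstance(v, np.ndarray) else preprocess_for_cnn(v, spec.input_shape)
        for v in volumes
    ]).astype(np.float32)[:, None]

    idx = np.arange(len(X))
    train_idx, hold_idx = train_test_split(
        idx, test_size=holdout_fraction, stratify=labels, random_state=seed
    )
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    result = ExperimentResult(combo="IMG", classifier="CNN3D", k=0)
    for fold, (tr, te) in enumerate(skf.split(train_idx, labels[train_idx])):
        tr_idx, te_idx = train_idx[tr], train_idx[te]
        model = CNN3D(replace(spec, seed=spec.seed + fold))
        train_cnn(model, X[tr_idx], labels[tr_idx])
        result.cv_accuracies.append(
            float((model.predict(X[te_idx]) == labels[te_idx]).mean())
        )
        result.holdout_accuracies.append(
            float((model.predict(X[hold_idx]) == labels[hold_idx]).mean())
        )
    return result
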