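"""3D convolutional autoencoder deep features.

The encoder stacks three {3x3x3 convolution -> LeakyReLU -> 2x max-pool}
blocks; the decoder mirrors them with nearest-neighbour up-sampling back to
the exact input shape (odd axes shrink under floor pooling, so each
up-sampling step restores its encoder counterpart's shape).  Training
minimises binary cross-entropy on [0,1]-scaled volumes with Adam.  Deep
features are the flattened bottleneck activations; a standard-deviation
filter keeps only informative ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FeatureTable, Volume3D
from .nn import Adam, Conv3D, LeakyReLU, MaxPool3D, Sequential, UpsampleTo, bce_with_logits, sigmoid

DEFAULT_INPUT_SHAPE = (22, 28, 40)


@dataclass
class AutoencoderSpec:
    input_shape: tuple[int, int, int] = DEFAULT_INPUT_SHAPE
    channels: tuple[int, int, int] = (16, 32, 64)
    leaky_alpha: float = 0.1
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 8
    seed: int = 0

    def pooled_shapes(self) -> list[tuple[int, int, int]]:
        """Spatial shape before each pool and at the bottleneck."""
        shapes = [tuple(self.input_shape)]
        cur = list(self.input_shape)
        for _ in range(3):
            for ax, n in enumerate(cur):
                if n // 2 < 1:
                    raise ValueError(
                        f"input_shape axis {ax} (size {self.input_shape[ax]}) collapses "
                        "under three 2x poolings"
                    )
                cur[ax] = n // 2
            shapes.append(tuple(cur))
        return shapes

    @property
    def bottleneck_dim(self) -> int:
        return int(np.prod(self.pooled_shapes()[-1])) * self.channels[-1]


class Autoencoder:
    """Model handle wrapping the encoder/decoder stack."""

    def __init__(self, spec: AutoencoderSpec):
        shapes = spec.pooled_shapes()  # validates pooling compatibility
        rng = np.random.default_rng(spec.seed)
        c1, c2, c3 = spec.channels
        a = spec.leaky_alpha
        enc = [
            Conv3D(1, c1, rng), LeakyReLU(a), MaxPool3D(),
            Conv3D(c1, c2, rng), LeakyReLU(a), MaxPool3D(),
            Conv3D(c2, c3, rng), LeakyReLU(a), MaxPool3D(),
        ]
        dec = [
            Conv3D(c3, c3, rng), LeakyReLU(a), UpsampleTo(shapes[2]),
            Conv3D(c3, c2, rng), LeakyReLU(a), UpsampleTo(shapes[1]),
            Conv3D(c2, c1, rng), LeakyReLU(a), UpsampleTo(shapes[0]),
            Conv3D(c1, 1, rng),  # reconstruction logits; sigmoid applied in the loss
        ]
        self.spec = spec
        self.model = Sequential(enc + dec)
        self._n_encoder_layers = len(enc)
        self.bottleneck_dim = spec.bottleneck_dim

    def encode(self, batch: np.ndarray) -> np.ndarray:
        x = batch
        for layer in self.model.layers[: self._n_encoder_layers]:
            x = layer.forward(x, train=False)
        return x.reshape(x.shape[0], -1)

    def reconstruct(self, batch: np.ndarray) -> np.ndarray:
        return sigmoid(self.model.forward(batch, train=False))

    @property
    def n_parameters(self) -> int:
        return self.model.n_parameters()


def build_autoencoder(spec: AutoencoderSpec | None = None) -> Autoencoder:
    return Autoencoder(spec or AutoencoderSpec())


def scale_unit(volume: Volume3D | np.ndarray) -> np.ndarray:
    """Per-volume min-max scaling to [0, 1]; a constant volume maps to 0."""
    data = volume.data if isinstance(volume, Volume3D) else np.asarray(volume)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        return np.zeros_like(data, dtype=np.float32)
    return ((data - lo) / (hi - lo)).astype(np.float32)


def _as_batch(volumes, input_shape) -> np.ndarray:
    arrs = []
    for v in volumes:
        data = v.data if isinstance(v, Volume3D) else np.asarray(v)
        if tuple(data.shape) != tuple(input_shape):
            raise ValueError(f"volume shape {data.shape} != expected {tuple(input_shape)}")
        arrs.append(np.asarray(data, np.float32))
    batch = np.stack(arrs)[:, None]
    if batch.min() < 0 or batch.max() > 1:
        raise ValueError("autoencoder inputs must be scaled to [0, 1] (see scale_unit)")
    return batch


def train_autoencoder(
    model: Autoencoder, volumes: list, spec: AutoencoderSpec | None = None
) -> tuple[Autoencoder, list[float]]:
    """Adam/BCE training; returns the model and one mean loss per epoch."""
    spec = spec or model.spec
    if len(volumes) < 2:
        raise ValueError("training requires at least 2 volumes")
    X = _as_batch(volumes, spec.input_shape)
    rng = np.random.default_rng(spec.seed + 1)
    opt = Adam(model.model, lr=spec.learning_rate)
    history: list[float] = []
    n = len(X)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb = X[idx]
            logits = model.model.forward(xb, train=True)
            loss, grad = bce_with_logits(logits, xb)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            model.model.backward(grad)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def extract_bottleneck(model: Autoencoder, volume: Volume3D | np.ndarray) -> np.ndarray:
    """Flattened bottleneck activation vector for one volume."""
    batch = _as_batch([volume], model.spec.input_shape)
    vec = model.encode(batch)[0]
    assert vec.size == model.bottleneck_dim
    return vec


def deep_feature_table(model: Autoencoder, volumes: dict) -> FeatureTable:
    """Bottleneck features for a keyed set of volumes as a DF-tagged table."""
    names = [f"df_{i + 1:04d}" for i in range(model.bottleneck_dim)]
    rows = {sid: extract_bottleneck(model, vol) for sid, vol in volumes.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    df.index.name = "subject_id"
    return FeatureTable(df, "DF")


def filter_by_std(
    table: FeatureTable, threshold: float = 0.25
) -> tuple[FeatureTable, list[str]]:
    """Keep feature columns whose standard deviation strictly exceeds ``threshold``.

    Returns the filtered table and the names of the dropped columns; an
    empty survivor set is allowed (flagged by the caller, not an error).
    """
    if table.shape[0] < 2:
        raise ValueError("std filter requires at least 2 rows")
    stds = table.values().std(axis=0)  # population (ddof=0) std
    keep = [c for c, s in zip(table.columns, stds) if s > threshold]
    dropped = [c for c in table.columns if c not in keep]
    if not keep:
        empty = table.df.iloc[:, :0]
        return FeatureTable(empty, {}), dropped
    return table.select(keep), dropped
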