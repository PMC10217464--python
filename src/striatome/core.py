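"""Core in-memory containers shared by every pipeline stage.

Conventions used throughout the package:

* all arrays are indexed ``(x, y, z)`` with 0-based indices;
* ``x`` is the lateral (left-right) axis, lower indices are the subject's left;
* spacing is millimetres per voxel, one value per axis;
* feature tables are pandas DataFrames indexed by ``subject_id`` with a
  provenance tag (``CF``/``RF``/``DF``) per column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: provenance families a feature column may belong to
FAMILIES = ("CF", "RF", "DF")


@dataclass
class Volume3D:
    """A 3D scalar image with voxel spacing in millimetres."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"Volume3D requires 3D data, got {self.data.ndim}D "
                f"with shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class ROIMask:
    """A binary mask aligned to a :class:`Volume3D` grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    side: str | None = None  # "left" / "right" when known

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("ROIMask requires 3D data")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not bool(self.data.any())


def dice(a: ROIMask | np.ndarray, b: ROIMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = a.data if isinstance(a, ROIMask) else np.asarray(a, bool)
    b = b.data if isinstance(b, ROIMask) else np.asarray(b, bool)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


class FeatureTable:
    """Subjects x named features with per-column provenance tags.

    Thin wrapper over a DataFrame indexed by ``subject_id``.  Tags travel
    with the columns so combined datasets can report family composition
    (e.g. "17 CFs and 3 DFs" among selected features).
    """

    def __init__(self, df: pd.DataFrame, tags: dict[str, str] | str | None = None):
        if df.index.name != "subject_id":
            if "subject_id" in df.columns:
                df = df.set_index("subject_id")
            else:
                df = df.copy()
                df.index.name = "subject_id"
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject_id values: {dupes}")
        self.df = df
        if tags is None:
            tags = {}
        if isinstance(tags, str):
            tags = {c: tags for c in df.columns}
        self.tags: dict[str, str] = {c: tags.get(c, "CF") for c in df.columns}

    # -- basic protocol ----------------------------------------------------
    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    @property
    def subjects(self) -> list:
        return list(self.df.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def select(self, columns: list[str]) -> "FeatureTable":
        return FeatureTable(self.df[columns], {c: self.tags[c] for c in columns})

    def family_counts(self, columns: list[str] | None = None) -> dict[str, int]:
        cols = columns if columns is not None else self.columns
        out = {f: 0 for f in FAMILIES}
        for c in cols:
            out[self.tags.get(c, "CF")] += 1
        return out

    @staticmethod
    def concat(tables: list["FeatureTable"]) -> "FeatureTable":
        keys = [set(t.subjects) for t in tables]
        common = set.intersection(*keys)
        missing = set.union(*keys) - common
        if missing:
            raise ValueError(
                f"subject keys do not match across tables; unmatched: {sorted(missing)}"
            )
        order = [s for s in tables[0].subjects if s in common]
        df = pd.concat([t.df.loc[order] for t in tables], axis=1)
        tags: dict[str, str] = {}
        for t in tables:
            tags.update(t.tags)
        return FeatureTable(df, tags)


@dataclass
class OutcomeLabels:
    """Per-subject binary cognitive outcome (0 = normal, 1 = abnormal)."""

    labels: pd.Series  # int {0,1}, indexed by subject_id

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)
        bad = set(self.labels.unique()) - {0, 1}
        if bad:
            raise ValueError(f"labels must be binary 0/1, found {sorted(bad)}")

    @property
    def subjects(self) -> list:
        return list(self.labels.index)

    def values(self) -> np.ndarray:
        return self.labels.to_numpy()

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())


@dataclass
class ExperimentResult:
    """Metrics for one (feature-set, classifier, k) cell of the benchmark."""

    combo: str
    classifier: str
    k: int
    cv_accuracies: list[float] = field(default_factory=list)
    holdout_accuracies: list[float] = field(default_factory=list)
    selected_features: list[str] = field(default_factory=list)
    selected_family_counts: dict[str, int] = field(default_factory=dict)
    tuned_params: dict = field(default_factory=dict)
    error: str | None = None

    @property
    def cv_mean(self) -> float:
        return float(np.mean(self.cv_accuracies)) if self.cv_accuracies else float("nan")

    @property
    def cv_std(self) -> float:
        return float(np.std(self.cv_accuracies, ddof=0)) if self.cv_accuracies else float("nan")

    @property
    def holdout_mean(self) -> float:
        return float(np.mean(self.holdout_accuracies)) if self.holdout_accuracies else float("nan")

    @property
    def holdout_std(self) -> float:
        return float(np.std(self.holdout_accuracies, ddof=0)) if self.holdout_accuracies else float("nan")

    def as_row(self) -> dict:
        return {
            "combo": self.combo,
            "classifier": self.classifier,
            "k": self.k,
            "cv_mean": self.cv_mean,
            "cv_std": self.cv_std,
            "holdout_mean": self.holdout_mean,
            "holdout_std": self.holdout_std,
            "n_selected": len(self.selected_features),
            "selected_cf": self.selected_family_counts.get("CF", 0),
            "selected_rf": self.selected_family_counts.get("RF", 0),
            "selected_df": self.selected_family_counts.get("DF", 0),
            "error": self.error or "",
        }
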