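"""NIfTI volume and CSV feature-table readers/writers.

Volumes round-trip through NIfTI-1 with spacing in the header zooms;
feature tables through CSV with a ``subject_id`` key column and provenance
encoded by a ``cf__``/``rf__``/``df__`` column-name prefix.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import FAMILIES, FeatureTable, ROIMask, Volume3D


class FileFormatError(RuntimeError):
    pass


def read_volume(path: str | Path) -> Volume3D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FileFormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FileFormatError(
            f"{path}: expected a 3D volume, got {data.ndim}D with shape {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(np.asarray(data, float), spacing)


def write_volume(volume: Volume3D, path: str | Path) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.data, np.float64), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> ROIMask:
    vol = read_volume(path)
    return ROIMask(vol.data > 0.5, vol.spacing)


def write_mask(mask: ROIMask, path: str | Path) -> None:
    affine = np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

_PREFIX = {f: f.lower() + "__" for f in FAMILIES}


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.df.copy()
    df.columns = [f"{_PREFIX[table.tags[c]]}{c}" for c in df.columns]
    df.to_csv(path, index=True)


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise FileFormatError(f"{path}: missing required 'subject_id' header column")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise FileFormatError(f"{path}: duplicate subject_id values {dupes}")
    df = df.set_index("subject_id")
    tags, cols = {}, {}
    for c in df.columns:
        tag = "CF"
        name = c
        for fam, pre in _PREFIX.items():
            if c.startswith(pre):
                tag, name = fam, c[len(pre):]
                break
        cols[c] = name
        tags[name] = tag
    df = df.rename(columns=cols)
    return FeatureTable(df.apply(pd.to_numeric), tags)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
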