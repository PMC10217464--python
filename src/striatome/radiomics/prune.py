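"""Low-variance and high-correlation feature pruning."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import FeatureTable


@dataclass
class DropRecord:
    feature: str
    reason: str  # "low variance" | "high correlation"
    detail: str = ""


def prune_features(
    table: FeatureTable,
    corr_threshold: float = 0.95,
    variance_threshold: float = 1e-12,
) -> tuple[FeatureTable, list[DropRecord]]:
    """Drop near-constant columns, then the later member of correlated pairs.

    Variance pruning removes columns with population variance at or below
    ``variance_threshold``.  Correlation pruning walks columns in original
    order and keeps the first of any pair whose absolute Pearson r meets
    ``corr_threshold`` (keep-first, greedy).  Returns the surviving table
    and a drop log.
    """
    if not (0 < corr_threshold <= 1):
        raise ValueError(f"corr_threshold must be in (0, 1], got {corr_threshold}")
    if variance_threshold < 0:
        raise ValueError("variance_threshold must be >= 0")

    X = table.values()
    cols = table.columns
    log: list[DropRecord] = []

    var = X.var(axis=0)
    keep = var > variance_threshold
    for c, v, k in zip(cols, var, keep):
        if not k:
            log.append(DropRecord(c, "low variance", f"variance={v:.3g}"))
    cols = [c for c, k in zip(cols, keep) if k]
    X = X[:, keep]
    if not cols:
        raise ValueError("pruning removed every feature (all low variance)")

    corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
    surviving: list[int] = []
    for j in range(len(cols)):
        partner = next(
            (i for i in surviving if abs(corr[i, j]) >= corr_threshold), None
        )
        if partner is None:
            surviving.append(j)
        else:
            log.append(
                DropRecord(
                    cols[j], "high correlation",
                    f"|r|={abs(corr[partner, j]):.3f} with {cols[partner]}",
                )
            )
    kept = [cols[j] for j in surviving]
    if not kept:
        raise ValueError("pruning removed every feature")
    return table.select(kept), log
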