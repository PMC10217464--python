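"""Grey-level discretization preceding texture-matrix construction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiscretizationConfig:
    method: str = "fixed_bin_number"  # or "fixed_bin_size"
    bins: int = 64
    bin_width: float = 1.0
    resegment_range: tuple[float, float] | None = None  # intensity clip window

    def validate(self) -> None:
        if self.method not in ("fixed_bin_number", "fixed_bin_size"):
            raise ValueError(f"unknown discretization method {self.method!r}")
        if self.method == "fixed_bin_number" and self.bins < 2:
            raise ValueError("fixed_bin_number requires bins >= 2")
        if self.method == "fixed_bin_size" and self.bin_width <= 0:
            raise ValueError("fixed_bin_size requires bin_width > 0")


def discretize(
    data: np.ndarray, mask: np.ndarray, config: DiscretizationConfig | None = None
) -> tuple[np.ndarray, int, bool]:
    """Map in-mask intensities to integer grey levels 1..G.

    Fixed-bin-number splits the in-mask [min, max] range into ``bins`` equal
    bins; the maximum lands in the top bin.  Fixed-bin-size uses bins of
    ``bin_width`` anchored at the (resegmented) minimum.  Returns
    ``(levels, n_levels, degenerate)`` where ``levels`` is 0 outside the
    mask and ``degenerate`` flags a constant ROI (all voxels level 1).
    """
    config = config or DiscretizationConfig()
    config.validate()
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("discretize requires a non-empty mask")
    data = np.asarray(data, float)
    vals = data[mask]
    if config.resegment_range is not None:
        lo, hi = config.resegment_range
        vals = np.clip(vals, lo, hi)
    vmin, vmax = float(vals.min()), float(vals.max())

    if config.method == "fixed_bin_number":
        if vmax <= vmin:
            levels_in = np.ones(vals.shape, int)
            degenerate = True
        else:
            g = np.floor(config.bins * (vals - vmin) / (vmax - vmin)).astype(int) + 1
            levels_in = np.minimum(g, config.bins)
            degenerate = False
        n_levels = int(levels_in.max())
    else:
        levels_in = np.floor((vals - vmin) / config.bin_width).astype(int) + 1
        degenerate = vmax <= vmin
        n_levels = int(levels_in.max())

    levels = np.zeros(data.shape, int)
    levels[mask] = levels_in
    return levels, n_levels, degenerate
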