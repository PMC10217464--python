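"""Automated dorsal-striatum segmentation.

A deterministic 12-step slice-wise chain: averaging smooth, CLAHE, two
contrast raises, a configured crop around the striata, order-statistic
filtering, summation, fractional-maximum thresholding, morphological
closing, lateral halving into left/right, and 2D-to-3D assembly, with an
optional QC overlay of mask contours on the input volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, morphology, segmentation as sk_seg

from .core import ROIMask, Volume3D


class SegmentationError(RuntimeError):
    """Structured failure carrying the pipeline step that produced it."""

    def __init__(self, step: int, message: str):
        super().__init__(f"step {step}: {message}")
        self.step = step


@dataclass
class SegmentationConfig:
    smooth_kernel: int = 3
    clahe_clip_limit: float = 0.005
    clahe_tile_grid: int = 4
    # fractional (lo, hi) per axis; the box must contain both striata
    crop_box: tuple[tuple[float, float], ...] = ((0.2, 0.8), (0.18, 0.82), (0.2, 0.8))
    osf_window: int = 3
    osf_rank: int | None = None  # default: median rank ceil(window^2 / 2)
    threshold_fraction: float = 0.40
    closing_radius: int = 2
    slice_axis: int = 2
    lateral_axis: int = 0
    keep_intermediate: bool = False

    def validate(self, shape=None) -> None:
        if not (0 < self.threshold_fraction < 1):
            raise ValueError(f"threshold_fraction must be in (0,1), got {self.threshold_fraction}")
        for name, w in (("smooth_kernel", self.smooth_kernel), ("osf_window", self.osf_window)):
            if w < 3 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3, got {w}")
        rank = self.resolved_rank
        if not (1 <= rank <= self.osf_window**2):
            raise ValueError(f"osf rank must be in [1, {self.osf_window ** 2}], got {rank}")
        for ax, (lo, hi) in enumerate(self.crop_box):
            if not (0 <= lo < hi <= 1):
                raise ValueError(f"crop_box axis {ax} fractions invalid: ({lo}, {hi})")
        if shape is not None:
            for ax, sl in enumerate(self.crop_slices(shape)):
                if sl.stop - sl.start < 2:
                    raise ValueError(f"crop_box collapses axis {ax} for shape {shape}")

    @property
    def resolved_rank(self) -> int:
        return self.osf_rank if self.osf_rank is not None else (self.osf_window**2 + 1) // 2

    def crop_slices(self, shape) -> tuple[slice, ...]:
        out = []
        for n, (lo, hi) in zip(shape, self.crop_box):
            a, b = int(round(lo * n)), int(round(hi * n))
            if a < 0 or b > n:
                raise ValueError(f"crop_box ({lo}, {hi}) outside volume axis of size {n}")
            out.append(slice(a, b))
        return tuple(out)


@dataclass
class SegmentationResult:
    left: ROIMask
    right: ROIMask
    less_affected_side: str  # hemisphere with the higher mean uptake
    qc_overlay: np.ndarray | None = None  # (n_slices, H, W, 3) uint8
    intermediate: dict[str, np.ndarray] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# primitive operators
# ---------------------------------------------------------------------------

def order_statistic_filter(image: np.ndarray, window: int, rank: int) -> np.ndarray:
    """Sliding-window order-statistic filter on a 2D image.

    Each output pixel is the ``rank``-th smallest (1-based) value in the
    ``window`` x ``window`` neighbourhood, with replicate padding at the
    borders.  ``rank = (window**2 + 1) // 2`` is the median filter.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("order_statistic_filter expects a 2D image")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if not (1 <= rank <= window**2):
        raise ValueError(f"rank must be in [1, {window ** 2}], got {rank}")
    return ndimage.rank_filter(image, rank - 1, size=window, mode="nearest")


def binarize_fraction(data: np.ndarray, fraction: float) -> tuple[np.ndarray, bool]:
    """Threshold at ``fraction`` of the global maximum (inclusive >=).

    Returns ``(mask, empty)``; an all-zero input yields an empty mask with
    the flag set rather than an exception.
    """
    data = np.asarray(data, float)
    vmax = float(data.max()) if data.size else 0.0
    if vmax <= 0:
        return np.zeros(data.shape, bool), True
    mask = data >= fraction * vmax
    return mask, not bool(mask.any())


def split_left_right(
    mask: np.ndarray, lateral_axis: int = 0
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Cut the mask at the lateral midpoint into (left, right) halves.

    Lower lateral indices are "left".  The cut assigns indices
    ``< ceil(n/2)`` to the left output, so for odd widths the midplane
    column goes left.  Voxel counts always partition the input.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("split_left_right requires a non-empty mask")
    n = mask.shape[lateral_axis]
    mid = (n + 1) // 2
    idx = np.arange(n)
    left_sel = idx < mid
    shape = [1] * mask.ndim
    shape[lateral_axis] = n
    left_sel = left_sel.reshape(shape)
    left = mask & left_sel
    right = mask & ~left_sel
    warnings = []
    if not left.any():
        warnings.append("left output empty: mask lies entirely on the right side")
    if not right.any():
        warnings.append("right output empty: mask lies entirely on the left side")
    return left, right, warnings


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _rescale_percentiles(image: np.ndarray, p_lo: float = 1.0) -> np.ndarray:
    """Contrast raise: linear stretch of [p1, max] onto [0, 1].

    Anchoring the top at the true maximum (not a high percentile) keeps the
    small striatal plateau from being clipped and the background floor from
    being amplified.
    """
    lo, hi = float(np.percentile(image, p_lo)), float(image.max())
    if hi <= lo:
        return np.zeros_like(image, dtype=float)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def _per_slice(volume: np.ndarray, slice_axis: int, fn) -> np.ndarray:
    moved = np.moveaxis(volume, slice_axis, 0)
    out = np.stack([fn(sl) for sl in moved])
    return np.moveaxis(out, 0, slice_axis)


def segment_striatum(volume: Volume3D, config: SegmentationConfig | None = None) -> SegmentationResult:
    """Run the full enhancement -> threshold -> halving chain on one volume.

    Steps, in order: (1) slice-wise averaging smooth; (2) slice-wise CLAHE;
    (3) global contrast raise; (4) crop to the configured striatal box;
    (5) contrast raise of the crop; (6) slice-wise order-statistic filter;
    (7) voxelwise sum of the cropped (4) and filtered (6) images;
    (8) threshold at ``threshold_fraction`` of the maximum; (9) slice-wise
    morphological closing; (10) lateral halving into left/right;
    (11) re-embedding of the 2D slice masks into full-grid 3D ROIs; a QC
    contour overlay is emitted alongside.

    The pipeline is fully deterministic; an empty thresholded mask raises a
    :class:`SegmentationError` naming step 8.
    """
    config = config or SegmentationConfig()
    config.validate(volume.shape)
    data = np.asarray(volume.data, float)
    ax = config.slice_axis
    inter: dict[str, np.ndarray] = {}

    # (1) averaging smooth per slice
    k = config.smooth_kernel
    sizes = [k, k, k]
    sizes[ax] = 1  # 2D smoothing within each slice
    smoothed = ndimage.uniform_filter(data, size=sizes, mode="nearest")

    # (2) CLAHE per slice; equalize_adapthist expects values in [0, 1]
    vmax = smoothed.max()
    norm = smoothed / vmax if vmax > 0 else smoothed

    def clahe2d(sl):
        peak = sl.max()
        if peak <= sl.min():
            return np.zeros_like(sl)
        eq = exposure.equalize_adapthist(
            sl / peak, kernel_size=max(2, min(sl.shape) // config.clahe_tile_grid * 2),
            clip_limit=config.clahe_clip_limit,
        )
        # restore the slice's global brightness so dim (striatum-free) slices
        # stay dim relative to the uptake plateau
        return eq * peak

    enhanced = _per_slice(norm, ax, clahe2d)

    # (3) global contrast raise
    raised = _rescale_percentiles(enhanced)

    # (4) crop to the striatal box
    crop_sl = config.crop_slices(data.shape)
    cropped = raised[crop_sl]

    # (5) contrast raise of the crop
    crop_raised = _rescale_percentiles(cropped)

    # (6) order-statistic filter per slice of the crop
    rank = config.resolved_rank
    filtered = _per_slice(crop_raised, ax, lambda sl: order_statistic_filter(sl, config.osf_window, rank))

    # (7) sum to enlarge the image surface
    summed = crop_raised + filtered

    # (8) fractional-maximum threshold
    mask, empty = binarize_fraction(summed, config.threshold_fraction)
    if empty:
        raise SegmentationError(8, "no voxel reaches the threshold; segmentation is empty")

    # (9) morphological closing, 2D disk per slice
    selem = morphology.disk(config.closing_radius)
    closed = _per_slice(mask, ax, lambda sl: ndimage.binary_closing(sl, structure=selem))

    # (10) lateral halving
    left2d, right2d, warns = split_left_right(closed, config.lateral_axis)

    # (11) assemble full-grid 3D ROIs
    full_left = np.zeros(data.shape, bool)
    full_right = np.zeros(data.shape, bool)
    full_left[crop_sl] = left2d
    full_right[crop_sl] = right2d

    mean_l = float(data[full_left].mean()) if full_left.any() else -np.inf
    mean_r = float(data[full_right].mean()) if full_right.any() else -np.inf
    less_affected = "left" if mean_l >= mean_r else "right"

    overlay = qc_overlay(data, full_left | full_right, ax)
    if config.keep_intermediate:
        inter = {
            "1_smoothed": smoothed, "2_clahe": enhanced, "3_raised": raised,
            "4_cropped": cropped, "5_crop_raised": crop_raised,
            "6_filtered": filtered, "7_summed": summed,
            "8_threshold": mask, "9_closed": closed,
        }
    return SegmentationResult(
        left=ROIMask(full_left, volume.spacing, side="left"),
        right=ROIMask(full_right, volume.spacing, side="right"),
        less_affected_side=less_affected,
        qc_overlay=overlay,
        intermediate=inter,
        warnings=warns,
    )


def qc_overlay(data: np.ndarray, mask: np.ndarray, slice_axis: int = 2) -> np.ndarray:
    """Greyscale volume slices with mask contours burned in red, uint8 RGB."""
    vol = np.moveaxis(data, slice_axis, 0)
    msk = np.moveaxis(mask, slice_axis, 0)
    vmax = vol.max() or 1.0
    grey = (255 * vol / vmax).astype(np.uint8)
    rgb = np.stack([grey] * 3, axis=-1)
    for i in range(rgb.shape[0]):
        edge = sk_seg.find_boundaries(msk[i], mode="outer")
        rgb[i][edge] = (255, 0, 0)
    return rgb
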