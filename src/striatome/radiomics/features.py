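"""Named feature statistics per family and the 215-feature extractor.

The full inventory is 29 shape + 20 first-order + 30 intensity-histogram +
136 texture features (co-occurrence 50, run length 32, size zone 16,
distance zone 16, grey-tone difference 5, grey-level dependence 17).
Directional families are reported under two aggregations: features averaged
over the 13 directions (``avg``) and features of the direction-merged
matrix (``mrg``).
"""

from __future__ import annotations

import warnings

import numpy as np

from ..core import ROIMask, Volume3D
from . import matrices as mx
from .discretize import DiscretizationConfig, discretize
from .shape import SHAPE_FEATURES, shape_features

# --------------------------------------------------------------------------
# name inventory
# --------------------------------------------------------------------------

FIRSTORDER_FEATURES = [
    "mean", "variance", "skewness", "kurtosis", "median", "minimum",
    "percentile_10", "percentile_90", "maximum", "interquartile_range",
    "range", "mean_abs_deviation", "robust_mean_abs_deviation",
    "median_abs_deviation", "coefficient_of_variation",
    "quartile_coefficient_dispersion", "energy", "root_mean_square",
    "standard_deviation", "sum",
]

INTHIST_FEATURES = [
    "mean", "variance", "skewness", "kurtosis", "median", "minimum",
    "percentile_10", "percentile_25", "percentile_75", "percentile_90",
    "maximum", "mode", "mode_probability", "interquartile_range", "range",
    "mean_abs_deviation", "robust_mean_abs_deviation", "median_abs_deviation",
    "coefficient_of_variation", "quartile_coefficient_dispersion", "entropy",
    "uniformity", "max_gradient", "max_gradient_level", "min_gradient",
    "min_gradient_level", "standard_deviation", "energy", "root_mean_square",
    "sum",
]

GLCM_FEATURES = [
    "joint_max", "joint_average", "joint_variance", "joint_entropy",
    "diff_average", "diff_variance", "diff_entropy",
    "sum_average", "sum_variance", "sum_entropy",
    "angular_second_moment", "contrast", "dissimilarity",
    "inverse_difference", "inverse_difference_norm",
    "inverse_difference_moment", "inverse_difference_moment_norm",
    "inverse_variance", "correlation", "autocorrelation",
    "cluster_tendency", "cluster_shade", "cluster_prominence",
    "info_correlation_1", "info_correlation_2",
]

GLRLM_FEATURES = [
    "short_run_emphasis", "long_run_emphasis",
    "low_gl_run_emphasis", "high_gl_run_emphasis",
    "short_run_low_gl_emphasis", "short_run_high_gl_emphasis",
    "long_run_low_gl_emphasis", "long_run_high_gl_emphasis",
    "gl_nonuniformity", "gl_nonuniformity_norm",
    "run_length_nonuniformity", "run_length_nonuniformity_norm",
    "run_percentage", "gl_variance", "run_length_variance", "run_entropy",
]

GLSZM_FEATURES = [
    "small_zone_emphasis", "large_zone_emphasis",
    "low_gl_zone_emphasis", "high_gl_zone_emphasis",
    "small_zone_low_gl_emphasis", "small_zone_high_gl_emphasis",
    "large_zone_low_gl_emphasis", "large_zone_high_gl_emphasis",
    "gl_nonuniformity", "gl_nonuniformity_norm",
    "zone_size_nonuniformity", "zone_size_nonuniformity_norm",
    "zone_percentage", "gl_variance", "zone_size_variance", "zone_size_entropy",
]

GLDZM_FEATURES = [
    "small_distance_emphasis", "large_distance_emphasis",
    "low_gl_zone_emphasis", "high_gl_zone_emphasis",
    "small_distance_low_gl_emphasis", "small_distance_high_gl_emphasis",
    "large_distance_low_gl_emphasis", "large_distance_high_gl_emphasis",
    "gl_nonuniformity", "gl_nonuniformity_norm",
    "zone_distance_nonuniformity", "zone_distance_nonuniformity_norm",
    "zone_percentage", "gl_variance", "zone_distance_variance",
    "zone_distance_entropy",
]

NGTDM_FEATURES = ["coarseness", "contrast", "busyness", "complexity", "strength"]

NGLDM_FEATURES = [
    "low_dependence_emphasis", "high_dependence_emphasis",
    "low_gl_count_emphasis", "high_gl_count_emphasis",
    "low_dependence_low_gl_emphasis", "low_dependence_high_gl_emphasis",
    "high_dependence_low_gl_emphasis", "high_dependence_high_gl_emphasis",
    "gl_nonuniformity", "gl_nonuniformity_norm",
    "dependence_count_nonuniformity", "dependence_count_nonuniformity_norm",
    "dependence_count_percentage", "gl_variance", "dependence_count_variance",
    "dependence_count_entropy", "dependence_count_energy",
]

FAMILY_ORDER = ["shape", "firstorder", "inthist", "cm", "rlm", "szm", "dzm", "ngtdm", "ngldm"]

FAMILY_COUNTS = {
    "shape": 29, "firstorder": 20, "inthist": 30,
    "cm": 50, "rlm": 32, "szm": 16, "dzm": 16, "ngtdm": 5, "ngldm": 17,
}


def feature_names(family: str) -> list[str]:
    """Fully qualified, order-stable names of one family."""
    if family == "shape":
        return [f"shape.{n}" for n in SHAPE_FEATURES]
    if family == "firstorder":
        return [f"fo.{n}" for n in FIRSTORDER_FEATURES]
    if family == "inthist":
        return [f"ih.{n}" for n in INTHIST_FEATURES]
    if family == "cm":
        return [f"cm.{agg}.{n}" for agg in ("avg", "mrg") for n in GLCM_FEATURES]
    if family == "rlm":
        return [f"rlm.{agg}.{n}" for agg in ("avg", "mrg") for n in GLRLM_FEATURES]
    if family == "szm":
        return [f"szm.{n}" for n in GLSZM_FEATURES]
    if family == "dzm":
        return [f"dzm.{n}" for n in GLDZM_FEATURES]
    if family == "ngtdm":
        return [f"ngtdm.{n}" for n in NGTDM_FEATURES]
    if family == "ngldm":
        return [f"ngldm.{n}" for n in NGLDM_FEATURES]
    raise ValueError(f"unknown feature family {family!r}")


ALL_FEATURE_NAMES: list[str] = [n for fam in FAMILY_ORDER for n in feature_names(fam)]
N_FEATURES_TOTAL = len(ALL_FEATURE_NAMES)  # 215


# --------------------------------------------------------------------------
# first-order / histogram statistics
# --------------------------------------------------------------------------

def _distribution_stats(x: np.ndarray) -> dict[str, float]:
    n = x.size
    mu = float(x.mean())
    var = float(x.var())  # population variance
    sd = float(np.sqrt(var))
    med = float(np.median(x))
    p10, p25, p75, p90 = (float(v) for v in np.percentile(x, [10, 25, 75, 90]))
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = float(np.mean((x - mu) ** 3) / sd**3) if sd > 0 else 0.0
        kurt = float(np.mean((x - mu) ** 4) / var**2 - 3.0) if var > 0 else 0.0
        cov = sd / mu if mu != 0 else float("nan")
        qcod = (p75 - p25) / (p75 + p25) if (p75 + p25) != 0 else float("nan")
    # robust MAD uses only values inside the [p10, p90] closed band
    band = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(band - band.mean()))) if band.size else 0.0
    return {
        "mean": mu, "variance": var, "skewness": skew, "kurtosis": kurt,
        "median": med, "minimum": float(x.min()), "percentile_10": p10,
        "percentile_25": p25, "percentile_75": p75, "percentile_90": p90,
        "maximum": float(x.max()), "interquartile_range": p75 - p25,
        "range": float(x.max() - x.min()),
        "mean_abs_deviation": float(np.mean(np.abs(x - mu))),
        "robust_mean_abs_deviation": rmad,
        "median_abs_deviation": float(np.mean(np.abs(x - med))),
        "coefficient_of_variation": cov,
        "quartile_coefficient_dispersion": qcod,
        "energy": float(np.sum(x.astype(float) ** 2)),
        "root_mean_square": float(np.sqrt(np.mean(x.astype(float) ** 2))),
        "standard_deviation": sd,
        "sum": float(x.sum()),
    }


def firstorder_features(vals: np.ndarray) -> dict[str, float]:
    s = _distribution_stats(np.asarray(vals, float))
    return {f"fo.{k}": s[k] for k in FIRSTORDER_FEATURES}


def inthist_features(levels_in_mask: np.ndarray, n_levels: int) -> dict[str, float]:
    x = np.asarray(levels_in_mask, float)
    s = _distribution_stats(x)
    counts = np.bincount(levels_in_mask.astype(int), minlength=n_levels + 1)[1:]
    p = counts / counts.sum()
    nz = p > 0
    mode_idx = int(np.argmax(counts))
    grad = np.gradient(counts.astype(float)) if n_levels > 1 else np.zeros(1)
    out = {k: s[k] for k in INTHIST_FEATURES if k in s}
    out.update({
        "mode": float(mode_idx + 1),
        "mode_probability": float(p[mode_idx]),
        "entropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "uniformity": float((p**2).sum()),
        "max_gradient": float(grad.max()),
        "max_gradient_level": float(np.argmax(grad) + 1),
        "min_gradient": float(grad.min()),
        "min_gradient_level": float(np.argmin(grad) + 1),
    })
    return {f"ih.{k}": out[k] for k in INTHIST_FEATURES}


# --------------------------------------------------------------------------
# co-occurrence statistics
# --------------------------------------------------------------------------

def glcm_statistics(M: np.ndarray) -> dict[str, float]:
    """The 25 co-occurrence features of one symmetric count matrix."""
    total = M.sum()
    if total == 0:
        return {k: float("nan") for k in GLCM_FEATURES}
    p = M / total
    G = p.shape[0]
    i = np.arange(1, G + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # symmetric: px == py
    nzp = p > 0

    mu = float((I * p).sum())
    joint_var = float(((I - mu) ** 2 * p).sum())
    joint_entropy = float(-(p[nzp] * np.log2(p[nzp])).sum())

    # difference and sum marginal distributions
    k_diff = np.arange(G)
    p_diff = np.array([p[np.abs(I - J) == k].sum() for k in k_diff])
    da = float((k_diff * p_diff).sum())
    k_sum = np.arange(2, 2 * G + 1)
    p_sum = np.array([p[(I + J) == k].sum() for k in k_sum])
    sa = float((k_sum * p_sum).sum())

    def _ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = np.sqrt(float((((I - mu) ** 2) * p).sum()))
        if sigma > 0:
            correlation = float(((I - mu) * (J - mu) * p).sum() / sigma**2)
        else:
            correlation = 1.0
        hx = _ent(px)
        hxy1 = float(-(p[nzp] * np.log2(np.outer(px, px)[nzp])).sum())
        op = np.outer(px, px)
        hxy2 = _ent(op.ravel())
        ic1 = (joint_entropy - hxy1) / hx if hx > 0 else 0.0
        ic2_arg = 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy))
        ic2 = float(np.sqrt(ic2_arg)) if ic2_arg > 0 else 0.0
        inv_var_terms = p[I != J] / ((I - J)[I != J] ** 2) if G > 1 else np.array([0.0])

    return {
        "joint_max": float(p.max()),
        "joint_average": mu,
        "joint_variance": joint_var,
        "joint_entropy": joint_entropy,
        "diff_average": da,
        "diff_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "diff_entropy": _ent(p_diff),
        "sum_average": sa,
        "sum_variance": float(((k_sum - sa) ** 2 * p_sum).sum()),
        "sum_entropy": _ent(p_sum),
        "angular_second_moment": float((p**2).sum()),
        "contrast": float(((I - J) ** 2 * p).sum()),
        "dissimilarity": float((np.abs(I - J) * p).sum()),
        "inverse_difference": float((p / (1 + np.abs(I - J))).sum()),
        "inverse_difference_norm": float((p / (1 + np.abs(I - J) / G)).sum()),
        "inverse_difference_moment": float((p / (1 + (I - J) ** 2)).sum()),
        "inverse_difference_moment_norm": float((p / (1 + ((I - J) / G) ** 2)).sum()),
        "inverse_variance": float(inv_var_terms.sum()),
        "correlation": correlation,
        "autocorrelation": float((I * J * p).sum()),
        "cluster_tendency": float(((I + J - 2 * mu) ** 2 * p).sum()),
        "cluster_shade": float(((I + J - 2 * mu) ** 3 * p).sum()),
        "cluster_prominence": float(((I + J - 2 * mu) ** 4 * p).sum()),
        "info_correlation_1": float(ic1),
        "info_correlation_2": ic2,
    }


# --------------------------------------------------------------------------
# generic level/count matrix statistics (run length, zones, dependence)
# --------------------------------------------------------------------------

def _rowcol_statistics(M: np.ndarray, n_voxels: int, names: list[str]) -> dict[str, float]:
    """The shared 16/17-feature scheme over a level x count matrix.

    Rows index grey level i = 1..G; columns index the counted quantity
    j = 1..L (run length, zone size, zone distance or dependence count + 1).
    ``names`` supplies the family's vocabulary in canonical order.
    """
    Ns = M.sum()
    if Ns == 0:
        return {k: float("nan") for k in names}
    G, L = M.shape
    i = np.arange(1, G + 1)[:, None].astype(float)
    j = np.arange(1, L + 1)[None, :].astype(float)
    p = M / Ns
    ri = M.sum(axis=1)  # per-level totals
    cj = M.sum(axis=0)  # per-count totals
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    nz = p > 0
    vals = [
        float((M / j**2).sum() / Ns),
        float((M * j**2).sum() / Ns),
        float((M / i**2).sum() / Ns),
        float((M * i**2).sum() / Ns),
        float((M / (i**2 * j**2)).sum() / Ns),
        float((M * i**2 / j**2).sum() / Ns),
        float((M * j**2 / i**2).sum() / Ns),
        float((M * i**2 * j**2).sum() / Ns),
        float((ri**2).sum() / Ns),
        float((ri**2).sum() / Ns**2),
        float((cj**2).sum() / Ns),
        float((cj**2).sum() / Ns**2),
        float(Ns / n_voxels),
        float((((i - mu_i) ** 2) * p).sum()),
        float((((j - mu_j) ** 2) * p).sum()),
        float(-(p[nz] * np.log2(p[nz])).sum()),
    ]
    if len(names) == 17:  # dependence family adds an energy term
        vals.append(float((p**2).sum()))
    return dict(zip(names, vals))


def ngtdm_statistics(s: np.ndarray, n: np.ndarray) -> dict[str, float]:
    """The five grey-tone-difference features from the (s_i, n_i) table."""
    Nv = n.sum()
    if Nv == 0:
        return {k: float("nan") for k in NGTDM_FEATURES}
    p = n / Nv
    present = p > 0
    i = np.arange(1, len(n) + 1).astype(float)
    Ngp = int(present.sum())
    ps = float((p * s).sum())

    coarseness = 1.0 / ps if ps > 0 else 1e6  # capped when perfectly smooth
    if Ngp > 1:
        ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
        pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
        si = np.meshgrid(s[present], s[present], indexing="ij")[0]
        sj = si.T
        contrast = float((pi * pj * (ii - jj) ** 2).sum() / (Ngp * (Ngp - 1)) * (s.sum() / Nv))
        denom_busy = float(np.abs(ii * pi - jj * pj).sum())
        busyness = ps / denom_busy if denom_busy > 0 else 0.0
        complexity = float((np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / Nv)
        ssum = float(s.sum())
        strength = float(((pi + pj) * (ii - jj) ** 2).sum() / ssum) if ssum > 0 else 0.0
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0
    return {
        "coarseness": coarseness, "contrast": contrast, "busyness": busyness,
        "complexity": complexity, "strength": strength,
    }


# --------------------------------------------------------------------------
# family extraction
# --------------------------------------------------------------------------

def _crop_to_mask(data: np.ndarray, mask: np.ndarray, pad: int = 1):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return data[sl], mask[sl]


def _aggregate_directional(mats: list[np.ndarray], stat_fn) -> tuple[dict, dict]:
    per_dir = [stat_fn(M) for M in mats]
    keys = per_dir[0].keys()
    avg = {k: float(np.mean([d[k] for d in per_dir])) for k in keys}
    width = max(M.shape[1] for M in mats)
    merged = np.zeros((mats[0].shape[0], width))
    for M in mats:
        merged[:, : M.shape[1]] += M
    mrg = stat_fn(merged)
    return avg, mrg


def extract_family(
    volume: Volume3D,
    mask: ROIMask,
    family: str,
    config: DiscretizationConfig | None = None,
) -> dict[str, float]:
    """Compute one family's named features for a single ROI."""
    if family not in FAMILY_ORDER:
        raise ValueError(f"unknown feature family {family!r}")
    data = np.asarray(volume.data, float)
    m = mask.data
    if not m.any():
        raise ValueError("extract_family requires a non-empty mask")

    if family == "shape":
        feats = shape_features(data, m, volume.spacing)
        return {f"shape.{k}": v for k, v in feats.items()}
    if family == "firstorder":
        return firstorder_features(data[m])

    cdata, cmask = _crop_to_mask(data, m)
    levels, G, degenerate = discretize(cdata, cmask, config)
    if degenerate and m.sum() > 1:
        warnings.warn(f"constant ROI: {family} features computed on a single grey level")
    n_vox = int(cmask.sum())

    if family == "inthist":
        return inthist_features(levels[cmask], G)
    if family == "cm":
        avg, mrg = _aggregate_directional(mx.glcm(levels, cmask, G), glcm_statistics)
        out = {f"cm.avg.{k}": v for k, v in avg.items()}
        out.update({f"cm.mrg.{k}": v for k, v in mrg.items()})
        return out
    if family == "rlm":
        fn = lambda M: _rowcol_statistics(M, n_vox, GLRLM_FEATURES)
        avg, mrg = _aggregate_directional(mx.glrlm(levels, cmask, G), fn)
        out = {f"rlm.avg.{k}": v for k, v in avg.items()}
        out.update({f"rlm.mrg.{k}": v for k, v in mrg.items()})
        return out
    if family == "szm":
        M = mx.glszm(levels, cmask, G)
        return {f"szm.{k}": v for k, v in _rowcol_statistics(M, n_vox, GLSZM_FEATURES).items()}
    if family == "dzm":
        M = mx.gldzm(levels, cmask, G)
        return {f"dzm.{k}": v for k, v in _rowcol_statistics(M, n_vox, GLDZM_FEATURES).items()}
    if family == "ngtdm":
        s, n = mx.ngtdm(levels, cmask, G)
        return {f"ngtdm.{k}": v for k, v in ngtdm_statistics(s, n).items()}
    if family == "ngldm":
        M = mx.ngldm(levels, cmask, G)
        return {f"ngldm.{k}": v for k, v in _rowcol_statistics(M, n_vox, NGLDM_FEATURES).items()}
    raise AssertionError(family)


def extract_all(
    volume: Volume3D, mask: ROIMask, config: DiscretizationConfig | None = None
) -> dict[str, float]:
    """All 215 features in fixed family order with stable names."""
    out: dict[str, float] = {}
    for family in FAMILY_ORDER:
        try:
            feats = extract_family(volume, mask, family, config)
        except Exception as exc:  # propagate with family context
            raise RuntimeError(f"feature family {family!r} failed: {exc}") from exc
        expected = feature_names(family)
        missing = [n for n in expected if n not in feats]
        if missing:
            raise RuntimeError(f"family {family!r} produced incomplete inventory: {missing}")
        out.update({n: feats[n] for n in expected})
    return out
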