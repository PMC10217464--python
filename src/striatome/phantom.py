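"""Synthetic DAT-SPECT phantoms and clinical cohorts with known ground truth.

The imaging phantom places two high-uptake ellipsoidal "striatal" bodies
(optionally comma-bent) on a uniform background, applies a Gaussian
point-spread blur and count noise, and reports noise-free ground-truth masks
so segmentation can be scored by Dice.  The cohort generator draws a
59-column clinical table and ties a binary year-4 cognitive outcome to a
subset of features through an explicit logistic model, so feature selection
and classifiers can be validated by parameter/signal recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import FeatureTable, OutcomeLabels, ROIMask, Volume3D

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class StriatalBody:
    """One ellipsoidal high-uptake body.

    ``bend`` curves the ellipsoid into a comma shape by shifting its lateral
    centre proportionally to the squared normalised anterior-posterior
    coordinate (0 = plain ellipsoid).
    """

    side: str  # "left" | "right"
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    uptake_contrast: float = 4.0
    bend: float = 0.0

    def support(self, grid_shape, voxel_size_mm) -> np.ndarray:
        """Boolean indicator of the body on the voxel grid (centre-of-volume origin)."""
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * s
            for n, s in zip(grid_shape, voxel_size_mm)
        ]
        x, y, z = np.meshgrid(*axes, indexing="ij")
        cx, cy, cz = self.center_mm
        ax, ay, az = self.semi_axes_mm
        yn = (y - cy) / ay
        # comma deformation: lateral centre drifts with y^2
        xc = cx + self.bend * ax * yn**2
        r2 = ((x - xc) / ax) ** 2 + yn**2 + ((z - cz) / az) ** 2
        return r2 <= 1.0


@dataclass
class PhantomSpec:
    """Configuration of one synthetic DAT-SPECT-like volume."""

    grid_shape: tuple[int, int, int] = (48, 56, 64)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    striatal_bodies: list[StriatalBody] = field(default_factory=lambda: default_bodies())
    psf_fwhm_mm: float = 6.0
    noise_model: str = "poisson"  # "poisson" | "gaussian"
    noise_scale: float = 1.0
    background_level: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ValueError(f"grid_shape axes must all be >= 8, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel size must be positive, got {self.voxel_size_mm}")
        for b in self.striatal_bodies:
            if any(a <= 0 for a in b.semi_axes_mm):
                raise ValueError(f"{b.side} body has non-positive semi-axis {b.semi_axes_mm}")
            if b.uptake_contrast <= 1:
                raise ValueError(
                    f"{b.side} body uptake_contrast must exceed 1, got {b.uptake_contrast}"
                )
        if self.noise_model not in ("poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        supports = [b.support(self.grid_shape, self.voxel_size_mm) for b in self.striatal_bodies]
        for i in range(len(supports)):
            for j in range(i + 1, len(supports)):
                if (supports[i] & supports[j]).any():
                    a, b = self.striatal_bodies[i], self.striatal_bodies[j]
                    raise ValueError(
                        f"striatal bodies overlap: {a.side} at {a.center_mm} and "
                        f"{b.side} at {b.center_mm}"
                    )


def default_bodies(uptake_contrast: float = 4.0, bend: float = 0.25) -> list[StriatalBody]:
    """Two mirrored comma-bent ellipsoids at +-13 mm laterally.

    Sized so both bodies fit inside the standard (22, 28, 40)-voxel analysis
    crop at 2 mm isotropic spacing.
    """
    semi = (7.0, 16.0, 9.0)
    return [
        StriatalBody("left", (-13.0, 2.0, 0.0), semi, uptake_contrast, bend),
        StriatalBody("right", (13.0, 2.0, 0.0), semi, uptake_contrast, bend),
    ]


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, ROIMask, ROIMask]:
    """Simulate one volume and its noise-free ground-truth striatal masks.

    The ideal image is background everywhere and ``background * contrast``
    inside each body; the PSF blur is applied before noise.  Ground truth for
    each side is the blurred (pre-noise) body signal thresholded at 50% of
    its own plateau — with zero blur this is the body support itself.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape, vox = spec.grid_shape, spec.voxel_size_mm
    sigma_vox = [spec.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in vox]

    ideal = np.full(shape, float(spec.background_level))
    masks: dict[str, np.ndarray] = {}
    for body in spec.striatal_bodies:
        sup = body.support(shape, vox)
        excess = spec.background_level * (body.uptake_contrast - 1.0)
        ideal[sup] += excess
        signal = np.where(sup, excess, 0.0)
        if spec.psf_fwhm_mm > 0:
            signal = gaussian_filter(signal, sigma_vox)
        masks[body.side] = signal >= 0.5 * excess

    blurred = gaussian_filter(ideal, sigma_vox) if spec.psf_fwhm_mm > 0 else ideal
    if spec.noise_scale > 0:
        if spec.noise_model == "poisson":
            # scale acts as counts-per-unit; larger scale = lower relative noise
            noisy = rng.poisson(np.maximum(blurred, 0.0) * spec.noise_scale) / spec.noise_scale
        else:
            noisy = blurred + rng.normal(0.0, spec.noise_scale, size=shape)
    else:
        noisy = blurred
    noisy = np.maximum(noisy, 0.0)

    vol = Volume3D(noisy, vox)
    left = ROIMask(masks.get("left", np.zeros(shape, bool)), vox, side="left")
    right = ROIMask(masks.get("right", np.zeros(shape, bool)), vox, side="right")
    return vol, left, right


# ---------------------------------------------------------------------------
# clinical cohort
# ---------------------------------------------------------------------------

#: study-condition demographics: 119 of 297 subjects male, age 61.11 +- 9.93 y
P_MALE = 119 / 297
AGE_MEAN, AGE_SD = 61.11, 9.93


def default_cf_schema() -> dict[str, dict]:
    """The 59-column clinical-feature schema.

    Named entries cover demographics, baseline cognition (MoCA, HVLT, Benton,
    letter-number sequencing, symbol-digit), motor scales (UPDRS parts,
    tremor/PIGD), autonomic/sleep/mood scales and a handful of binary
    genetic-risk markers; the remainder are generic standard-normal
    covariates standing in for the unpublished long tail.
    """
    schema: dict[str, dict] = {
        "age": {"dist": "normal", "mean": AGE_MEAN, "sd": AGE_SD},
        "sex_male": {"dist": "bernoulli", "p": P_MALE},
        "education_years": {"dist": "normal", "mean": 15.5, "sd": 3.0},
        "moca_baseline": {"dist": "normal", "mean": 27.1, "sd": 2.3},
        "hvlt_total_recall": {"dist": "normal", "mean": 24.4, "sd": 5.0},
        "hvlt_delayed_recall": {"dist": "normal", "mean": 8.4, "sd": 2.5},
        "hvlt_retention": {"dist": "normal", "mean": 0.85, "sd": 0.15},
        "hvlt_recognition": {"dist": "normal", "mean": 11.0, "sd": 1.2},
        "benton_judgement": {"dist": "normal", "mean": 12.8, "sd": 2.1},
        "letter_number_seq": {"dist": "normal", "mean": 10.6, "sd": 2.7},
        "semantic_fluency": {"dist": "normal", "mean": 48.7, "sd": 11.6},
        "symbol_digit": {"dist": "normal", "mean": 41.2, "sd": 9.7},
        "updrs1": {"dist": "normal", "mean": 5.6, "sd": 4.1},
        "updrs2": {"dist": "normal", "mean": 5.9, "sd": 4.2},
        "updrs3": {"dist": "normal", "mean": 20.9, "sd": 8.9},
        "updrs_total": {"dist": "normal", "mean": 32.4, "sd": 13.1},
        "tremor_score": {"dist": "normal", "mean": 0.47, "sd": 0.29},
        "pigd_score": {"dist": "normal", "mean": 0.22, "sd": 0.18},
        "hoehn_yahr": {"dist": "normal", "mean": 1.6, "sd": 0.5},
        "schwab_england": {"dist": "normal", "mean": 93.0, "sd": 5.9},
        "scopa_aut": {"dist": "normal", "mean": 9.5, "sd": 6.2},
        "epworth_sleepiness": {"dist": "normal", "mean": 5.8, "sd": 3.5},
        "rbd_questionnaire": {"dist": "normal", "mean": 4.1, "sd": 2.7},
        "gds_depression": {"dist": "normal", "mean": 2.3, "sd": 2.4},
        "stai_state": {"dist": "normal", "mean": 32.9, "sd": 10.4},
        "stai_trait": {"dist": "normal", "mean": 32.2, "sd": 9.6},
        "quip_icd": {"dist": "bernoulli", "p": 0.2},
        "upsit_total": {"dist": "normal", "mean": 22.3, "sd": 8.2},
        "family_history_pd": {"dist": "bernoulli", "p": 0.25},
        "handedness_right": {"dist": "bernoulli", "p": 0.89},
        "disease_duration_months": {"dist": "normal", "mean": 6.6, "sd": 6.5},
        "apoe_e4_carrier": {"dist": "bernoulli", "p": 0.26},
        "gba_mutation": {"dist": "bernoulli", "p": 0.09},
        "lrrk2_mutation": {"dist": "bernoulli", "p": 0.02},
        "snca_risk_allele": {"dist": "bernoulli", "p": 0.35},
        "mapt_h1h1": {"dist": "bernoulli", "p": 0.62},
    }
    i = 1
    while len(schema) < 59:
        schema[f"covariate_{i:02d}"] = {"dist": "normal", "mean": 0.0, "sd": 1.0}
        i += 1
    return schema


def default_outcome_model() -> dict:
    """Logistic model for P(abnormal year-4 outcome | standardised features).

    Lower baseline cognition, higher age and motor burden raise risk.  The
    intercept sets prevalence near 40% abnormal, in the balanced range a
    binary benchmark needs.
    """
    return {
        "intercept": -0.5,
        "coefficients": {
            "age": 0.5,
            "moca_baseline": -1.0,
            "hvlt_total_recall": -0.6,
            "updrs3": 0.4,
        },
    }


@dataclass
class CohortSpec:
    """Configuration of one synthetic clinical cohort."""

    n_subjects: int = 297
    cf_schema: dict[str, dict] = field(default_factory=default_cf_schema)
    outcome_model: dict = field(default_factory=default_outcome_model)
    label_cutoff: float = 26.0  # MoCA > cutoff = normal
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in self.outcome_model.get("coefficients", {}):
            if name not in self.cf_schema:
                raise ValueError(
                    f"outcome_model coefficient refers to unknown feature {name!r}"
                )


def _draw_feature(rng: np.random.Generator, dist: dict, n: int) -> np.ndarray:
    kind = dist["dist"]
    if kind == "normal":
        return rng.normal(dist["mean"], dist["sd"], n)
    if kind == "bernoulli":
        return (rng.random(n) < dist["p"]).astype(float)
    if kind == "uniform":
        return rng.uniform(dist["low"], dist["high"], n)
    raise ValueError(f"unknown distribution {kind!r}")


def _standardise(x: np.ndarray, dist: dict) -> np.ndarray:
    """Standardise by the schema's *population* moments (not the sample's)."""
    if dist["dist"] == "normal":
        return (x - dist["mean"]) / dist["sd"]
    if dist["dist"] == "bernoulli":
        p = dist["p"]
        return (x - p) / np.sqrt(p * (1 - p))
    if dist["dist"] == "uniform":
        lo, hi = dist["low"], dist["high"]
        return (x - (lo + hi) / 2) / ((hi - lo) / np.sqrt(12))
    raise ValueError(dist["dist"])


def generate_cohort(spec: CohortSpec) -> tuple[FeatureTable, OutcomeLabels, pd.Series]:
    """Simulate the clinical table, year-4 outcome labels and MoCA scores.

    The abnormal-outcome probability of each subject is the logistic
    transform of the outcome model's linear predictor over population-
    standardised features.  A year-4 MoCA score is then drawn consistently
    with the realised outcome (<= cutoff when abnormal, > cutoff when
    normal), so labels are exactly the deterministic cutoff rule applied to
    the returned scores.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    cols = {name: _draw_feature(rng, dist, n) for name, dist in spec.cf_schema.items()}

    eta = np.full(n, float(spec.outcome_model.get("intercept", 0.0)))
    for name, beta in spec.outcome_model.get("coefficients", {}).items():
        eta += beta * _standardise(cols[name], spec.cf_schema[name])
    p_abnormal = 1.0 / (1.0 + np.exp(-eta))
    abnormal = rng.random(n) < p_abnormal

    cutoff = spec.label_cutoff
    # year-4 MoCA drawn on each side of the cutoff (score range 0..30)
    lo_scores = rng.integers(max(0, int(cutoff) - 12), int(cutoff) + 1, n)
    hi_scores = rng.integers(int(cutoff) + 1, 31, n)
    moca = np.where(abnormal, lo_scores, hi_scores).astype(float)

    subject_ids = [f"S{i:04d}" for i in range(n)]
    df = pd.DataFrame(cols, index=pd.Index(subject_ids, name="subject_id"))
    table = FeatureTable(df, "CF")
    moca_series = pd.Series(moca, index=df.index, name="moca_year4")
    labels = OutcomeLabels(pd.Series((moca <= cutoff).astype(int), index=df.index, name="abnormal"))
    return table, labels, moca_series


def generate_labeled_phantoms(
    labels: np.ndarray,
    base_spec: PhantomSpec | None = None,
    contrast_by_label: tuple[float, float] = (4.0, 2.0),
    contrast_jitter: float = 0.0,
    seed: int = 0,
) -> list[tuple[Volume3D, ROIMask, ROIMask]]:
    """One phantom per label; uptake contrast encodes the class.

    Class 0 subjects get ``contrast_by_label[0]`` (intact uptake), class 1
    subjects the lower value (dopaminergic deficit) — the imaging analogue
    of the outcome signal the classifiers must recover.  ``contrast_jitter``
    adds per-subject log-normal biological variability (relative SD) so the
    class distributions overlap realistically; 0 gives perfectly separable
    classes.
    """
    base = base_spec or PhantomSpec()
    ss = np.random.SeedSequence(seed)
    jrng = np.random.default_rng(ss.spawn(1)[0])
    out = []
    for lab, child in zip(labels, ss.spawn(len(labels))):
        contrast = contrast_by_label[int(lab)]
        if contrast_jitter > 0:
            contrast = max(1.2, contrast * float(np.exp(jrng.normal(0.0, contrast_jitter))))
        bodies = [replace(b, uptake_contrast=contrast) for b in base.striatal_bodies]
        spec = replace(base, striatal_bodies=bodies, seed=int(child.generate_state(1)[0] % (2**31)))
        out.append(generate_phantom(spec))
    return out
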