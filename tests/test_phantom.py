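"""Phantom and cohort generators: construction, determinism, recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from striatome.phantom import (
    AGE_MEAN,
    AGE_SD,
    CohortSpec,
    PhantomSpec,
    StriatalBody,
    default_bodies,
    generate_cohort,
    generate_labeled_phantoms,
    generate_phantom,
)


class TestGeneratePhantom:
    def test_noise_free_construction_values(self):
        """Without blur or noise, body centres carry background*contrast and
        the outside carries exactly the background level."""
        bodies = default_bodies(uptake_contrast=5.0, bend=0.0)
        spec = PhantomSpec(
            striatal_bodies=bodies, psf_fwhm_mm=0.0, noise_scale=0.0,
            background_level=10.0,
        )
        vol, left, right = generate_phantom(spec)
        # voxel at the left body centre (mm -> index)
        shape, vox = spec.grid_shape, spec.voxel_size_mm
        idx = tuple(
            int(round(c / s + (n - 1) / 2))
            for c, s, n in zip(bodies[0].center_mm, vox, shape)
        )
        assert vol.data[idx] == 50.0
        assert vol.data[0, 0, 0] == 10.0
        assert vol.data.min() >= 0
        np.testing.assert_array_equal(left.data, bodies[0].support(shape, vox))

    def test_same_seed_bit_identical(self):
        a, _, _ = generate_phantom(PhantomSpec(seed=5))
        b, _, _ = generate_phantom(PhantomSpec(seed=5))
        np.testing.assert_array_equal(a.data, b.data)

    def test_uptake_contrast_visible_over_noise(self):
        """Across re-simulations, in-mask mean exceeds background mean by a
        margin far above the noise floor of the empirical means."""
        inside, outside = [], []
        for s in range(100):
            vol, left, right = generate_phantom(PhantomSpec(noise_model="gaussian",
                                                            noise_scale=1.0, seed=s))
            both = left.data | right.data
            inside.append(vol.data[left.data].mean())
            outside.append(vol.data[~both].mean())
        inside, outside = np.array(inside), np.array(outside)
        margin = inside.mean() - outside.mean()
        noise_scale = np.sqrt(inside.var() + outside.var())
        assert margin > 10 * noise_scale

    def test_masks_disjoint_and_aligned(self, default_phantom):
        vol, left, right = default_phantom
        assert not (left.data & right.data).any()
        assert left.shape == vol.shape == right.shape
        assert left.n_voxels > 0 and right.n_voxels > 0

    def test_overlapping_bodies_rejected(self):
        bodies = [
            StriatalBody("left", (-2.0, 0.0, 0.0), (8.0, 8.0, 8.0), 4.0),
            StriatalBody("right", (2.0, 0.0, 0.0), (8.0, 8.0, 8.0), 4.0),
        ]
        with pytest.raises(ValueError, match="overlap.*left.*right"):
            generate_phantom(PhantomSpec(striatal_bodies=bodies))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="spacing|voxel"):
            PhantomSpec(voxel_size_mm=(0.0, 2.0, 2.0)).validate()
        with pytest.raises(ValueError, match="contrast"):
            PhantomSpec(striatal_bodies=default_bodies(uptake_contrast=0.9)).validate()
        with pytest.raises(ValueError, match="grid_shape"):
            PhantomSpec(grid_shape=(4, 56, 64)).validate()


class TestGenerateCohort:
    def test_table_dimensions_and_label_law(self):
        table, labels, moca = generate_cohort(CohortSpec(n_subjects=120, seed=0))
        assert table.shape == (120, 59)
        # labels are exactly the cutoff rule applied to the returned scores
        np.testing.assert_array_equal(labels.values(), (moca <= 26).astype(int))
        assert 0 < labels.prevalence < 1

    def test_zero_model_gives_half_prevalence(self):
        spec = CohortSpec(n_subjects=2000,
                          outcome_model={"intercept": 0.0, "coefficients": {}}, seed=1)
        _, labels, _ = generate_cohort(spec)
        # binomial 95% CI around 0.5 at n = 2000
        assert abs(labels.prevalence - 0.5) < 1.96 * 0.5 / np.sqrt(2000)

    def test_strong_negative_intercept_gives_near_zero_prevalence(self):
        spec = CohortSpec(n_subjects=500,
                          outcome_model={"intercept": -10.0, "coefficients": {}}, seed=2)
        _, labels, _ = generate_cohort(spec)
        assert labels.prevalence < 0.01

    def test_age_distribution_matches_study_conditions(self):
        table, _, _ = generate_cohort(CohortSpec(n_subjects=2000, seed=3))
        age = table.df["age"]
        se_mean = AGE_SD / np.sqrt(2000)
        assert abs(age.mean() - AGE_MEAN) < 3 * se_mean
        se_sd = AGE_SD / np.sqrt(2 * 2000)
        assert abs(age.std(ddof=1) - AGE_SD) < 3 * se_sd

    def test_logistic_refit_recovers_coefficient(self):
        """Maximum-likelihood refit on the simulated table recovers an
        injected coefficient of +2 on a standardised feature."""
        spec = CohortSpec(
            n_subjects=2000,
            outcome_model={"intercept": 0.0, "coefficients": {"age": 2.0}},
            seed=4,
        )
        table, labels, _ = generate_cohort(spec)
        z = (table.df["age"].to_numpy() - AGE_MEAN) / AGE_SD
        fit = sm.Logit(labels.values(), sm.add_constant(z)).fit(disp=0)
        assert abs(fit.params[1] - 2.0) < 0.3

    def test_unknown_coefficient_rejected_by_name(self):
        spec = CohortSpec(outcome_model={"intercept": 0, "coefficients": {"nope": 1.0}})
        with pytest.raises(ValueError, match="nope"):
            generate_cohort(spec)

    def test_same_seed_identical_tables(self):
        a, la, ma = generate_cohort(CohortSpec(n_subjects=50, seed=9))
        b, lb, mb = generate_cohort(CohortSpec(n_subjects=50, seed=9))
        pd.testing.assert_frame_equal(a.df, b.df)
        np.testing.assert_array_equal(la.values(), lb.values())


def test_labeled_phantoms_follow_contrast_map():
    labels = np.array([0, 1, 0, 1])
    out = generate_labeled_phantoms(labels, contrast_by_label=(5.0, 2.0), seed=0)
    means = []
    for (vol, left, right), lab in zip(out, labels):
        means.append(vol.data[left.data | right.data].mean())
    assert means[0] > means[1] and means[2] > means[3]
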