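"""Discretization, feature inventory, invariances and pruning."""

import numpy as np
import pandas as pd
import pytest

from striatome.core import FeatureTable, ROIMask, Volume3D
from striatome.radiomics import (
    ALL_FEATURE_NAMES,
    DiscretizationConfig,
    FAMILY_COUNTS,
    FAMILY_ORDER,
    extract_all,
    extract_family,
    feature_names,
    prune_features,
)
from striatome.radiomics.discretize import discretize


class TestDiscretize:
    def test_two_bins_split_range_in_halves(self):
        data = np.array([0.0, 1.0, 2.0, 3.0]).reshape(1, 1, 4)
        mask = np.ones_like(data, bool)
        levels, G, degen = discretize(data, mask, DiscretizationConfig(bins=2))
        np.testing.assert_array_equal(levels.ravel(), [1, 1, 2, 2])
        assert G == 2 and not degen

    def test_constant_roi_flagged_degenerate(self):
        data = np.full((2, 2, 2), 4.2)
        levels, G, degen = discretize(data, np.ones((2, 2, 2), bool))
        assert degen and G == 1 and set(levels.ravel()) == {1}

    def test_matches_bin_edge_oracle(self):
        rng = np.random.default_rng(1)
        data = rng.random((5, 5, 4))
        mask = np.ones(data.shape, bool)
        cfg = DiscretizationConfig(bins=4)
        levels, G, _ = discretize(data, mask, cfg)
        lo, hi = data.min(), data.max()
        edges = lo + (hi - lo) * np.arange(1, 4) / 4
        expected = 1 + np.searchsorted(edges, data, side="right")
        expected = np.minimum(expected, 4)
        np.testing.assert_array_equal(levels, expected)


class TestInventory:
    def test_total_is_215_with_stable_order(self, default_phantom):
        vol, left, _ = default_phantom
        feats = extract_all(vol, left)
        assert list(feats) == ALL_FEATURE_NAMES
        assert len(feats) == 215

    @pytest.mark.parametrize("family", FAMILY_ORDER)
    def test_per_family_counts(self, family, default_phantom):
        vol, left, _ = default_phantom
        feats = extract_family(vol, left, family)
        assert len(feats) == FAMILY_COUNTS[family]
        assert set(feats) == set(feature_names(family))

    def test_all_finite_on_phantom_roi(self, default_phantom):
        vol, left, _ = default_phantom
        feats = extract_all(vol, left)
        bad = {k: v for k, v in feats.items() if not np.isfinite(v)}
        assert not bad

    def test_deterministic(self, small_roi):
        vol, mask = small_roi
        a = extract_all(vol, mask)
        b = extract_all(vol, mask)
        assert a == b


class TestFeatureValues:
    def test_firstorder_on_constant_roi(self):
        vol = Volume3D(np.full((3, 3, 3), 4.0))
        mask = ROIMask(np.ones((3, 3, 3), bool))
        feats = extract_family(vol, mask, "firstorder")
        assert feats["fo.mean"] == 4.0
        assert feats["fo.variance"] == 0.0

    def test_shape_voxel_volume_of_cuboid(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[2:4, 2:4, 2:4] = True  # 8 voxels
        vol = Volume3D(np.ones((6, 6, 6)), (1.0, 1.0, 1.0))
        feats = extract_family(vol, ROIMask(mask), "shape")
        assert feats["shape.volume_voxel"] == pytest.approx(8.0)

    def test_rotation_invariance_of_merged_features(self, small_roi):
        """A 90-degree grid rotation must leave shape volume, first-order,
        histogram and direction-merged texture features unchanged."""
        vol, mask = small_roi
        rot_vol = Volume3D(np.rot90(vol.data, axes=(0, 1)).copy(), vol.spacing)
        rot_mask = ROIMask(np.rot90(mask.data, axes=(0, 1)).copy(), mask.spacing)
        a = extract_all(vol, mask)
        b = extract_all(rot_vol, rot_mask)
        invariant = (
            ["shape.volume_voxel", "shape.volume_mesh", "shape.surface_area"]
            + feature_names("firstorder")
            + feature_names("inthist")
            + [n for n in feature_names("cm") if ".mrg." in n]
            + [n for n in feature_names("rlm") if ".mrg." in n]
            + feature_names("szm")
            + feature_names("ngtdm")
            + feature_names("ngldm")
        )
        for name in invariant:
            assert a[name] == pytest.approx(b[name], abs=1e-9), name

    def test_intensity_shift_equivariance(self, small_roi):
        """Adding a constant shifts the first-order mean by that constant and
        leaves fixed-bin-number texture features unchanged."""
        vol, mask = small_roi
        shifted = Volume3D(vol.data + 100.0, vol.spacing)
        a = extract_all(vol, mask)
        b = extract_all(shifted, mask)
        assert b["fo.mean"] == pytest.approx(a["fo.mean"] + 100.0)
        for fam in ("cm", "rlm", "szm", "dzm", "ngtdm", "ngldm"):
            for name in feature_names(fam):
                assert a[name] == pytest.approx(b[name], rel=1e-9), name

    def test_empty_mask_rejected(self):
        vol = Volume3D(np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match="non-empty"):
            extract_family(vol, ROIMask(np.zeros((3, 3, 3), bool)), "firstorder")


class TestPruneFeatures:
    @staticmethod
    def _table(arrays: dict) -> FeatureTable:
        df = pd.DataFrame(arrays)
        df.index = [f"S{i}" for i in range(len(df))]
        df.index.name = "subject_id"
        return FeatureTable(df, "RF")

    def test_constant_column_dropped_for_low_variance(self):
        rng = np.random.default_rng(0)
        t = self._table({"a": rng.random(10), "const": np.full(10, 3.0)})
        out, log = prune_features(t)
        assert out.columns == ["a"]
        assert log[0].feature == "const" and log[0].reason == "low variance"

    def test_exact_copy_drops_exactly_one(self):
        rng = np.random.default_rng(1)
        x = rng.random(20)
        t = self._table({"x": x, "y": x.copy(), "z": rng.random(20)})
        out, log = prune_features(t)
        assert out.columns == ["x", "z"]
        assert log[0].feature == "y" and log[0].reason == "high correlation"

    def test_matches_exhaustive_correlation_oracle(self):
        rng = np.random.default_rng(2)
        base = rng.random((50, 20))
        # inject some correlated pairs
        base[:, 5] = base[:, 1] * 0.99 + 0.01 * rng.random(50)
        base[:, 17] = -base[:, 3] + 0.01 * rng.random(50)
        t = self._table({f"f{i:02d}": base[:, i] for i in range(20)})
        out, _ = prune_features(t, corr_threshold=0.95)
        # oracle: greedy keep-first on the full correlation matrix
        corr = np.corrcoef(base, rowvar=False)
        survivors = []
        for j in range(20):
            if all(abs(corr[i, j]) < 0.95 for i in survivors):
                survivors.append(j)
        assert out.columns == [f"f{i:02d}" for i in survivors]

    def test_all_constant_rejected(self):
        t = self._table({"a": np.ones(5), "b": np.full(5, 2.0)})
        with pytest.raises(ValueError, match="every feature"):
            prune_features(t)
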