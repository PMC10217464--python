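"""Autoencoder construction, training behaviour and the std filter."""

import numpy as np
import pandas as pd
import pytest

from striatome.core import FeatureTable
from striatome.deep_features import (
    AutoencoderSpec,
    build_autoencoder,
    extract_bottleneck,
    filter_by_std,
    scale_unit,
    train_autoencoder,
)

SMALL = AutoencoderSpec(input_shape=(8, 8, 8), channels=(2, 3, 4), epochs=3, seed=0)


def _volumes(n, shape=(8, 8, 8), seed=0):
    rng = np.random.default_rng(seed)
    return [rng.random(shape).astype(np.float32) for _ in range(n)]


class TestBuild:
    def test_parameter_count_closed_form_single_channel(self):
        """With one channel everywhere, each 3x3x3 convolution holds 27
        weights + 1 bias; the stack has 7 convolutions."""
        spec = AutoencoderSpec(input_shape=(8, 8, 8), channels=(1, 1, 1))
        model = build_autoencoder(spec)
        assert model.n_parameters == 7 * (27 + 1)

    def test_reconstruction_shape_matches_input(self):
        model = build_autoencoder(SMALL)
        x = np.stack(_volumes(2))[:, None]
        assert model.reconstruct(x).shape == x.shape

    def test_default_spec_reports_bottleneck_dim(self):
        spec = AutoencoderSpec()
        # (22,28,40) -> (11,14,20) -> (5,7,10) -> (2,3,5), 64 channels
        assert spec.pooled_shapes()[-1] == (2, 3, 5)
        assert spec.bottleneck_dim == 2 * 3 * 5 * 64

    def test_incompatible_input_shape_rejected_naming_axis(self):
        with pytest.raises(ValueError, match="axis 0"):
            AutoencoderSpec(input_shape=(4, 16, 16)).pooled_shapes()

    def test_same_seed_identical_initial_weights(self):
        a = build_autoencoder(SMALL)
        b = build_autoencoder(SMALL)
        for la, lb in zip(a.model.layers, b.model.layers):
            for name in la.params:
                np.testing.assert_array_equal(la.params[name], lb.params[name])


class TestTrain:
    def test_history_length_equals_epochs(self):
        model = build_autoencoder(SMALL)
        _, hist = train_autoencoder(model, _volumes(4))
        assert len(hist) == 3

    def test_loss_decreases_on_small_set(self):
        spec = AutoencoderSpec(input_shape=(8, 8, 8), channels=(2, 3, 4),
                               epochs=15, seed=1)
        model = build_autoencoder(spec)
        _, hist = train_autoencoder(model, _volumes(6, seed=1))
        assert hist[-1] < hist[0]

    def test_overfits_single_repeated_volume(self):
        """Training on one repeated compressible binary volume drives the
        cross-entropy toward its (near-zero) noise floor."""
        vol = np.zeros((8, 8, 8), np.float32)
        vol[2:6, 2:6, 2:6] = 1.0  # a centred box fits through the bottleneck
        spec = AutoencoderSpec(input_shape=(8, 8, 8), channels=(2, 3, 4),
                               epochs=60, learning_rate=5e-3, seed=2)
        model = build_autoencoder(spec)
        _, hist = train_autoencoder(model, [vol] * 4)
        assert hist[-1] < 0.5 * hist[0]

    def test_reproducible_history_under_seed(self):
        h = []
        for _ in range(2):
            model = build_autoencoder(SMALL)
            _, hist = train_autoencoder(model, _volumes(4))
            h.append(hist)
        assert h[0] == h[1]

    def test_fewer_than_two_volumes_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            train_autoencoder(build_autoencoder(SMALL), _volumes(1))

    def test_out_of_range_intensities_rejected(self):
        model = build_autoencoder(SMALL)
        bad = [v * 3.0 for v in _volumes(3)]
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            train_autoencoder(model, bad)


class TestExtract:
    def test_deterministic_and_correct_length(self):
        model = build_autoencoder(SMALL)
        vol = _volumes(1)[0]
        a = extract_bottleneck(model, vol)
        b = extract_bottleneck(model, vol)
        np.testing.assert_array_equal(a, b)
        assert a.size == model.bottleneck_dim

    def test_zero_net_zero_input_gives_zero_bottleneck(self):
        model = build_autoencoder(SMALL)
        for layer in model.model.layers:
            for name in layer.params:
                layer.params[name][:] = 0.0
        vec = extract_bottleneck(model, np.zeros((8, 8, 8), np.float32))
        np.testing.assert_array_equal(vec, 0.0)

    def test_shape_mismatch_rejected(self):
        model = build_autoencoder(SMALL)
        with pytest.raises(ValueError, match="shape"):
            extract_bottleneck(model, np.zeros((9, 8, 8), np.float32))


def test_scale_unit_bounds_and_degenerate_rule():
    rng = np.random.default_rng(0)
    v = rng.normal(size=(4, 4, 4)) * 50
    u = scale_unit(v)
    assert u.min() == 0.0 and u.max() == 1.0
    np.testing.assert_array_equal(scale_unit(np.full((3, 3, 3), 9.9)), 0.0)


class TestFilterByStd:
    @staticmethod
    def _table(cols):
        df = pd.DataFrame(cols)
        df.index = [f"S{i}" for i in range(len(df))]
        df.index.name = "subject_id"
        return FeatureTable(df, "DF")

    def test_constant_column_dropped(self):
        t = self._table({"a": [0.0, 1.0, 2.0, 3.0], "c": [5.0] * 4})
        out, dropped = filter_by_std(t, 0.25)
        assert out.columns == ["a"] and dropped == ["c"]

    def test_std_exactly_at_threshold_dropped_strict(self):
        # two values 0 and 0.5: population std is exactly 0.25
        t = self._table({"edge": [0.0, 0.5], "keep": [0.0, 1.0]})
        out, dropped = filter_by_std(t, 0.25)
        assert dropped == ["edge"] and out.columns == ["keep"]

    def test_matches_direct_std_oracle(self):
        rng = np.random.default_rng(3)
        cols = {f"f{i}": rng.normal(0, rng.random(), 30) for i in range(12)}
        t = self._table(cols)
        out, _ = filter_by_std(t, 0.25)
        expected = [c for c in cols if np.asarray(cols[c]).std() > 0.25]
        assert out.columns == expected

    def test_empty_survivors_allowed(self):
        t = self._table({"a": [0.0, 0.1], "b": [1.0, 1.05]})
        out, dropped = filter_by_std(t, 0.25)
        assert out.shape[1] == 0 and set(dropped) == {"a", "b"}
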