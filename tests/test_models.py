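"""Architecture declarations, closed-form shape inference vs runtime probes,
parameter accounting vs per-tensor enumeration, and spec serialization."""

import numpy as np
import pytest

from crossphys.models import (
    LayerSpec,
    ModelSpec,
    TrainHyper,
    build_model,
    count_parameters,
    infer_shapes,
    seizure_model_spec,
    sleep_model_spec,
    spec_from_dict,
    spec_to_dict,
)

# printed output shapes of the two architectures (length, channels);
# vector layers carry length None
SEIZURE_SHAPES = [
    ("conv1d_1", 2556, 32),
    ("batch_normalization_1", 2556, 32),
    ("max_pooling1d_1", 2554, 32),
    ("conv1d_2", 1273, 64),
    ("batch_normalization_2", 1273, 64),
    ("max_pooling1d_2", 1271, 64),
    ("conv1d_3", 631, 64),
    ("batch_normalization_3", 631, 64),
    ("max_pooling1d_3", 629, 64),
    ("conv1d_4", 620, 128),
    ("batch_normalization_4", 620, 128),
    ("max_pooling1d_4", 618, 128),
    ("global_average_pooling1d", None, 128),
    ("dense_1", None, 256),
    ("dense_2", None, 128),
    ("dense_3", None, 2),
]

SLEEP_SHAPES = [
    ("conv1d_1", 2996, 16),
    ("batch_normalization_1", 2996, 16),
    ("conv1d_2", 2992, 16),
    ("batch_normalization_2", 2992, 16),
    ("average_pooling1d_1", 1496, 16),
    ("conv1d_3", 1492, 32),
    ("batch_normalization_3", 1492, 32),
    ("conv1d_4", 1488, 32),
    ("batch_normalization_4", 1488, 32),
    ("average_pooling1d_2", 744, 32),
    ("conv1d_5", 740, 32),
    ("batch_normalization_5", 740, 32),
    ("global_average_pooling1d", None, 32),
    ("dense_1", None, 32),
    ("dense_2", None, 5),
]


class TestSpecs:
    def test_seizure_layer_census(self):
        spec = seizure_model_spec()
        kinds = [l.kind for l in spec.layers]
        assert kinds.count("conv1d") == 4
        assert kinds.count("batch_norm") == 4
        assert kinds.count("max_pool1d") == 4
        assert kinds.count("global_avg_pool") == 1  # the fifth pooling layer
        assert spec.layers[-1].units == 2
        assert len(spec.feature_layer_names()) == 12

    def test_sleep_blocks(self):
        spec = sleep_model_spec()
        assert set(spec.block_boundaries) == {"block_1", "block_2", "block_3"}
        b1 = [spec.layer(n).kind for n in spec.block_boundaries["block_1"]]
        assert b1 == ["conv1d", "batch_norm", "conv1d", "batch_norm", "avg_pool1d"]
        b3 = [spec.layer(n).kind for n in spec.block_boundaries["block_3"]]
        assert b3 == ["conv1d", "batch_norm", "global_avg_pool"]
        assert spec.layers[-1].units == 5

    def test_serialization_round_trip(self):
        for spec in (seizure_model_spec(), sleep_model_spec()):
            assert spec_from_dict(spec_to_dict(spec)) == spec

    def test_spec_must_end_with_classifier(self):
        with pytest.raises(ValueError):
            ModelSpec(
                layers=(LayerSpec("dense_1", "dense", units=7),),
                input_len=10,
                input_channels=1,
                n_classes=2,
            )

    def test_hyper_validation(self):
        with pytest.raises(ValueError):
            TrainHyper(lr=1e-4, min_lr=1e-3)


class TestShapeInference:
    @pytest.mark.parametrize(
        "spec_fn,expected", [(seizure_model_spec, SEIZURE_SHAPES), (sleep_model_spec, SLEEP_SHAPES)]
    )
    def test_closed_form_matches_printed_tables(self, spec_fn, expected):
        shapes = infer_shapes(spec_fn())
        assert [(s.name, s.length, s.channels) for s in shapes] == expected

    def test_too_short_input_names_layer(self):
        spec = ModelSpec(
            layers=(
                LayerSpec("conv1d_1", "conv1d", filter_size=9, n_filters=4, stride=1),
                LayerSpec("global_average_pooling1d", "global_avg_pool"),
                LayerSpec("dense_1", "dense", units=2),
            ),
            input_len=5,
            input_channels=1,
            n_classes=2,
        )
        with pytest.raises(ValueError, match="conv1d_1"):
            infer_shapes(spec)

    @pytest.mark.parametrize("spec_fn", [seizure_model_spec, sleep_model_spec])
    def test_runtime_forward_shapes_equal_closed_form(self, spec_fn):
        spec = spec_fn()
        net = build_model(spec, seed=0)
        x = np.random.default_rng(0).standard_normal((2, 1, spec.input_len)).astype(np.float32)
        out = np.ascontiguousarray(x.transpose(0, 2, 1))  # engine-internal layout
        for layer, s in zip(net.layers, infer_shapes(spec)):
            out = layer.forward(out, training=False)
            if out.ndim == 3:
                assert out.shape[1:] == (s.length, s.channels), layer.name
            else:
                assert out.shape[1] == s.channels, layer.name


class TestBuildModel:
    def test_seeded_init_reproducible(self):
        a = build_model(sleep_model_spec(), seed=42)
        b = build_model(sleep_model_spec(), seed=42)
        sa, sb = a.get_state(), b.get_state()
        assert sa.keys() == sb.keys()
        assert all(np.array_equal(sa[k], sb[k]) for k in sa)
        c = build_model(sleep_model_spec(), seed=43)
        assert any(not np.array_equal(sa[k], c.get_state()[k]) for k in sa)

    def test_output_rows_softmax_normalized(self):
        net = build_model(sleep_model_spec(), seed=0)
        x = np.random.default_rng(1).standard_normal((4, 1, 3000)).astype(np.float32)
        p = net.predict_proba(x)
        assert p.shape == (4, 5)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()


class TestParameterCounts:
    @pytest.mark.parametrize("spec_fn", [seizure_model_spec, sleep_model_spec])
    def test_total_matches_tensor_enumeration(self, spec_fn):
        spec = spec_fn()
        net = build_model(spec, seed=0)
        enumerated = sum(layer.n_params for layer in net.layers)
        total, trainable = count_parameters(spec)
        assert total == enumerated == trainable

    def test_freezing_all_features_leaves_dense_only(self):
        spec = seizure_model_spec()
        frozen = frozenset(spec.feature_layer_names())
        _, trainable = count_parameters(spec, frozen)
        dense_params = (128 * 256 + 256) + (256 * 128 + 128) + (128 * 2 + 2)
        assert trainable == dense_params

    def test_monotone_under_subset(self):
        spec = seizure_model_spec()
        feature = spec.feature_layer_names()
        prev = count_parameters(spec, frozenset())[1]
        for depth in (3, 6, 9, 12):
            cur = count_parameters(spec, frozenset(feature[:depth]))[1]
            assert cur < prev
            prev = cur

    def test_unknown_layer_rejected(self):
        with pytest.raises(KeyError, match="conv1d_99"):
            count_parameters(seizure_model_spec(), frozenset({"conv1d_99"}))
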