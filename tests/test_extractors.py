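import numpy as np
import pytest

from volfuse.extractors import (TrainConfig, build_extractor, extract_features,
                                fc_concat_max, stack_features, train_extractor)


class TestBuildExtractor:
    def test_variant3_manifest_2_3_2_convs_and_3_pools(self):
        spec = build_extractor("cnn_variant3", (16, 16, 16), width_scale=0.1)
        kinds = [k for _, k, _ in spec.layer_manifest]
        assert kinds.count("conv3d") == 7
        assert kinds.count("maxpool3d") == 3
        conv_names = [p["name"] for _, k, p in spec.layer_manifest
                      if k == "conv3d"]
        blocks = [n.split("_")[0] for n in conv_names]
        assert [blocks.count(b) for b in ("b1", "b2", "b3")] == [2, 3, 2]

    def test_variant3_tap_points_resolve(self):
        spec = build_extractor("cnn_variant3", (16, 16, 16), width_scale=0.1)
        assert {"FC1", "FC2", "FC3"} <= set(spec.tap_points)
        indices = {i for i, _, _ in spec.layer_manifest}
        assert spec.tap_points["FC1"] in indices
        assert spec.tap_points["FC2"] in indices

    def test_resnet15_five_residual_stages(self):
        spec = build_extractor("resnet15", (16, 16, 16), width_scale=0.1)
        kinds = [k for _, k, _ in spec.layer_manifest]
        assert kinds.count("residual_block") == 5
        assert kinds.count("conv_block") == 2
        dense = [p for _, k, p in spec.layer_manifest if k == "dense"]
        assert dense[0]["units"] == 1000
        # the 1000-wide tap sits at manifest index 14
        assert spec.tap_points["FC4"] == 14

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown extractor kind"):
            build_extractor("vgg", (16, 16, 16))

    def test_incompatible_shape(self):
        with pytest.raises(ValueError, match="incompatible"):
            build_extractor("cnn_variant3", (4, 4, 4))

    def test_manifest_json_exports(self):
        spec = build_extractor("cnn_base", (8, 8, 8), width_scale=0.1)
        import json
        doc = json.loads(spec.manifest_json())
        assert doc["kind"] == "cnn_base"
        assert doc["layers"][0]["kind"] == "input"


class TestTrainExtractor:
    def test_zero_epochs_no_update(self, small_phantoms):
        spec = build_extractor("cnn_base", (16, 16, 16), width_scale=0.1,
                               fc_width=32, seed=0)
        before = spec.network["fc1"].w.copy()
        _, history = train_extractor(spec, small_phantoms,
                                     TrainConfig(epochs=0))
        assert history["epoch"] == []
        np.testing.assert_array_equal(spec.network["fc1"].w, before)

    def test_training_learns_easy_phantoms(self, small_phantoms):
        spec = build_extractor("cnn_variant2", (16, 16, 16), width_scale=0.15,
                               fc_width=64, seed=0)
        cfg = TrainConfig(epochs=12, batch_size=4, learning_rate=1e-3, seed=0)
        _, history = train_extractor(spec, small_phantoms, cfg)
        assert history["train_acc"][-1] >= 0.75
        assert len(history["epoch"]) <= 12

    def test_determinism(self, small_phantoms):
        results = []
        for _ in range(2):
            spec = build_extractor("cnn_base", (16, 16, 16), width_scale=0.1,
                                   fc_width=32, seed=5)
            _, history = train_extractor(
                spec, small_phantoms,
                TrainConfig(epochs=3, batch_size=4, seed=5))
            results.append(history["val_loss"])
        assert results[0] == results[1]

    def test_empty_data_rejected(self):
        spec = build_extractor("cnn_base", (16, 16, 16), width_scale=0.1)
        with pytest.raises(ValueError, match="empty"):
            train_extractor(spec, [], TrainConfig())

    def test_single_class_rejected(self, small_phantoms):
        spec = build_extractor("cnn_base", (16, 16, 16), width_scale=0.1)
        one_class = [v for v in small_phantoms if v.label == 0]
        with pytest.raises(ValueError, match="2 classes"):
            train_extractor(spec, one_class, TrainConfig())

    def test_bad_configs(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(split=(0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            TrainConfig(optimizer="rmsprop")


@pytest.fixture(scope="module")
def cnn_spec():
    return build_extractor("cnn_variant3", (16, 16, 16), width_scale=0.1,
                           fc_width=1000, seed=1)


class TestExtractFeatures:
    def test_fc1_width_1000(self, cnn_spec, small_phantoms):
        fm = extract_features(cnn_spec, small_phantoms, "FC1")
        assert fm.values.shape == (12, 1000)
        assert fm.feature_provenance[0] == ("cnn_variant3", "FC1")

    def test_fc4_on_resnet_width_1000(self, small_phantoms):
        spec = build_extractor("resnet15", (16, 16, 16), width_scale=0.1,
                               fc_width=1000, seed=1)
        fm = extract_features(spec, small_phantoms, "FC4")
        assert fm.values.shape == (12, 1000)

    def test_fc3_is_elementwise_max_of_fc1_fc2(self, cnn_spec, small_phantoms):
        f1 = extract_features(cnn_spec, small_phantoms, "FC1")
        f2 = extract_features(cnn_spec, small_phantoms, "FC2")
        f3 = extract_features(cnn_spec, small_phantoms, "FC3")
        np.testing.assert_allclose(f3.values,
                                   np.maximum(f1.values, f2.values))

    def test_unknown_tap(self, cnn_spec, small_phantoms):
        with pytest.raises(KeyError, match="FC9"):
            extract_features(cnn_spec, small_phantoms, "FC9")

    def test_deterministic_given_weights(self, cnn_spec, small_phantoms):
        a = extract_features(cnn_spec, small_phantoms, "FC1")
        b = extract_features(cnn_spec, small_phantoms, "FC1")
        np.testing.assert_array_equal(a.values, b.values)

    def test_feature_budget_2000(self, cnn_spec, small_phantoms):
        f3 = extract_features(cnn_spec, small_phantoms, "FC3")
        resnet = build_extractor("resnet15", (16, 16, 16), width_scale=0.1,
                                 fc_width=1000, seed=2)
        f4 = extract_features(resnet, small_phantoms, "FC4")
        stacked = stack_features(f3, f4)
        assert stacked.values.shape == (12, 2000)

    def test_linear_probe_on_noiseless_phantoms(self):
        from sklearn.linear_model import LogisticRegression

        from volfuse.synthetic import PhantomConfig, gen_volumes
        vols = gen_volumes(PhantomConfig(n_samples=9, shape=(16, 16, 16),
                                         noise_sd=0.0, jitter_voxels=0,
                                         seed=3))
        spec = build_extractor("cnn_variant3", (16, 16, 16), width_scale=0.1,
                               fc_width=64, seed=3)
        fm = extract_features(spec, vols, "FC1")
        y = [v.label for v in vols]
        probe = LogisticRegression(max_iter=2000).fit(fm.values, y)
        assert probe.score(fm.values, y) >= 0.95


class TestFcConcatMax:
    def test_elementwise_max(self):
        np.testing.assert_array_equal(
            fc_concat_max([1, 3, 2], [2, 1, 4]), [2, 3, 4])

    def test_equal_vectors_taken_once(self):
        x = np.array([0.5, -1.0, 2.0])
        out = fc_concat_max(x, x)
        np.testing.assert_array_equal(out, x)
        assert out.shape == x.shape

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            fc_concat_max([1, 2], [1, 2, 3])

    def test_dominates_inputs_commutative_idempotent(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.standard_normal(20)
            b = rng.standard_normal(20)
            m = fc_concat_max(a, b)
            assert np.all(m >= a) and np.all(m >= b)
            np.testing.assert_array_equal(m, fc_concat_max(b, a))
            np.testing.assert_array_equal(m, fc_concat_max(m, m))
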