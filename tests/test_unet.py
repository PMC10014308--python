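"""U-Net module surface: specs, schedules, patch streams, tiled inference."""

import numpy as np
import pytest

from lfseg.synthetic import scene_to_training_pairs
from lfseg.unet import (
    PatchSampler,
    TrainingConfig,
    UNetSpec,
    build_model,
    load_model,
    published2d,
    published3d,
    predict_probability_map,
    sample_patches,
    save_model,
    train,
)


class TestUNetSpec:
    def test_published_2d_filter_progression(self):
        spec = UNetSpec(dims=2)
        assert spec.encoder_filters == [64, 128, 256, 512]
        assert spec.bottleneck_filters == 1024

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError, match="dims"):
            UNetSpec(dims=4)

    def test_output_shape_and_probability_normalization(self):
        model = build_model(UNetSpec(dims=2, encoder_depth=2, first_layer_filters=4))
        x = np.random.default_rng(0).random((1, 1, 32, 32))
        probs = model.net.predict_proba(x)
        assert probs.shape == (1, 3, 32, 32)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_parameter_count_deterministic(self):
        spec = UNetSpec(dims=2, encoder_depth=2, first_layer_filters=8)
        assert build_model(spec, seed=1).net.n_parameters() == build_model(
            spec, seed=2
        ).net.n_parameters()


class TestTrainingConfig:
    def test_published_2d_schedule(self):
        cfg = published2d()
        assert cfg.patch_shape == (256, 256)
        assert cfg.batch_size == 12
        assert cfg.epochs == 50
        assert cfg.optimizer == "sgdm"
        assert cfg.initial_lr == 0.05
        assert (cfg.lr_drop_period, cfg.lr_drop_factor) == (10, 0.1)
        assert cfg.momentum == 0.9
        assert cfg.l2_regularization == 1e-4
        assert published2d(ffpe=True).epochs == 150

    def test_published_3d_schedule(self):
        cfg = published3d()
        assert cfg.patch_shape == (64, 64, 64)
        assert cfg.batch_size == 8
        assert cfg.epochs == 150
        assert cfg.optimizer == "adam"
        assert cfg.initial_lr == 5e-4
        assert (cfg.lr_drop_period, cfg.lr_drop_factor) == (5, 0.95)

    def test_invalid_optimizer_rejected(self):
        with pytest.raises(ValueError, match="optimizer"):
            TrainingConfig(optimizer="adagrad")


class TestPatchSampler:
    def _image_labels(self, shape=(64, 64), seed=0):
        rng = np.random.default_rng(seed)
        return rng.random(shape), rng.integers(0, 3, size=shape)

    def test_image_equal_to_patch_returns_it(self):
        image, labels = self._image_labels((64, 64))
        cfg = TrainingConfig(patch_shape=(64, 64), augment=False, patches_per_epoch=4)
        stream = iter(sample_patches(image, labels, cfg))
        patch, lab = next(stream)
        assert np.array_equal(patch, image) and np.array_equal(lab, labels)

    def test_seeded_stream_is_reproducible(self):
        image, labels = self._image_labels((128, 128))
        cfg = TrainingConfig(patch_shape=(64, 64), patches_per_epoch=8, seed=11)
        a = [p for p, _ in zip(iter(sample_patches(image, labels, cfg)), range(20))]
        b = [p for p, _ in zip(iter(sample_patches(image, labels, cfg)), range(20))]
        for (pa, la), (pb, lb) in zip(a, b):
            assert np.array_equal(pa, pb) and np.array_equal(la, lb)

    def test_augmentation_covers_dihedral_group(self):
        # an asymmetric patch must appear in all 8 axis-aligned variants
        image = np.zeros((8, 8))
        image[0, 1] = 1.0
        image[2, 0] = 0.5
        labels = np.zeros((8, 8), dtype=int)
        cfg = TrainingConfig(
            patch_shape=(8, 8), augment=True, patches_per_epoch=64, seed=0
        )
        seen = set()
        stream = iter(sample_patches(image, labels, cfg))
        for _ in range(200):
            patch, _ = next(stream)
            seen.add(patch.tobytes())
        assert len(seen) == 8

    def test_small_image_reflect_padded(self):
        image, labels = self._image_labels((40, 40))
        cfg = TrainingConfig(patch_shape=(64, 64), patches_per_epoch=2)
        patch, lab = next(iter(sample_patches(image, labels, cfg)))
        assert patch.shape == (64, 64) and lab.shape == (64, 64)

    def test_input_mean_matches_source(self):
        image, labels = self._image_labels((64, 64))
        sampler = sample_patches(image, labels, TrainingConfig(patch_shape=(64, 64)))
        assert sampler.input_mean == pytest.approx(float(image.mean()))


class TestTraining:
    def test_degenerate_single_class_converges_fast(self):
        rng = np.random.default_rng(0)
        image = rng.random((64, 64))
        labels = np.zeros((64, 64), dtype=int)
        spec = UNetSpec(dims=2, encoder_depth=1, first_layer_filters=4)
        cfg = TrainingConfig(
            patch_shape=(32, 32), batch_size=4, epochs=5, optimizer="adam",
            initial_lr=5e-2, lr_drop_period=5, lr_drop_factor=0.5,
            patches_per_epoch=32, seed=1,
        )
        model = build_model(spec, seed=1)
        _, history = train(model, sample_patches(image, labels, cfg), cfg)
        assert history[-1] < 0.05
        assert history[-1] < history[0]

    def test_training_is_seed_reproducible(self):
        rng = np.random.default_rng(3)
        image = rng.random((64, 64))
        labels = (image > 0.5).astype(int)
        spec = UNetSpec(dims=2, encoder_depth=1, first_layer_filters=4)
        cfg = TrainingConfig(
            patch_shape=(32, 32), batch_size=2, epochs=2, optimizer="adam",
            initial_lr=1e-3, patches_per_epoch=8, seed=7,
        )
        runs = []
        for _ in range(2):
            model = build_model(spec, seed=7)
            _, hist = train(model, sample_patches(image, labels, cfg), cfg)
            runs.append((hist, model.net.state_dict()))
        assert runs[0][0] == runs[1][0]
        for k in runs[0][1]:
            assert np.array_equal(runs[0][1][k], runs[1][1][k])


@pytest.fixture(scope="module")
def toy_model():
    return build_model(UNetSpec(dims=2, encoder_depth=2, first_layer_filters=4), seed=0)


class TestPrediction:

    def test_single_tile_equals_direct_output(self, toy_model, rng):
        image = rng.random((64, 64))
        direct = toy_model.net.predict_proba(image[None, None].astype(np.float32))[0]
        tiled = predict_probability_map(toy_model, image, tile_shape=None)
        assert np.allclose(tiled, direct, atol=1e-6)

    def test_constant_input_invariant_modulo_upsampling_grid(self, toy_model):
        # strided up-convolutions make the output periodic with period
        # 2**depth; away from borders a constant input must reproduce that
        # pattern exactly (translation invariance modulo the stride grid)
        probs = predict_probability_map(toy_model, np.full((64, 64), 0.5))
        grid = 2**toy_model.spec.encoder_depth
        interior = probs[:, 24:40, 24:40]
        for dy in range(grid):
            for dx in range(grid):
                phase = interior[:, dy::grid, dx::grid]
                spread = phase.max(axis=(1, 2)) - phase.min(axis=(1, 2))
                assert (spread < 1e-3).all()

    def test_tiled_close_to_untiled_on_trained_model(self, pipeline2d):
        # feathered tile blending must agree with whole-image inference
        model = pipeline2d["model"]
        image, _ = scene_to_training_pairs(pipeline2d["eval_scene"])
        untiled = predict_probability_map(model, image)
        tiled = predict_probability_map(
            model, image, tile_shape=(128, 128), overlap_fraction=0.30
        )
        assert np.abs(tiled - untiled).max() < 0.05

    def test_probabilities_sum_to_one(self, toy_model, rng):
        probs = predict_probability_map(
            toy_model, rng.random((96, 96)), tile_shape=(64, 64), overlap_fraction=0.2
        )
        assert np.allclose(probs.sum(axis=0), 1.0, atol=1e-5)

    def test_dims_mismatch_rejected(self, toy_model, rng):
        with pytest.raises(ValueError, match="dimensions"):
            predict_probability_map(toy_model, rng.random((8, 8, 8)))

    def test_invalid_overlap_rejected(self, toy_model, rng):
        with pytest.raises(ValueError, match="overlap"):
            predict_probability_map(toy_model, rng.random((64, 64)), (32, 32), 0.7)


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path, rng):
        model = build_model(UNetSpec(dims=2, encoder_depth=1, first_layer_filters=4), seed=5)
        model.input_mean = 0.37
        model.trained = True
        path = tmp_path / "model.npz"
        save_model(model, path, published2d())
        restored = load_model(path)
        assert restored.spec == model.spec
        assert restored.input_mean == pytest.approx(0.37)
        x = rng.random((32, 32))
        assert np.allclose(
            predict_probability_map(model, x), predict_probability_map(restored, x)
        )
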