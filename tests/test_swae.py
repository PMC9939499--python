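"""Autoencoder contracts: determinism, loss structure, training, fine-tuning."""

import dataclasses

import numpy as np
import pytest

import ultratrack as ut
from ultratrack import swae
from ultratrack.swae import sample_ball_prior, sliced_wasserstein


def quick_config(**kw):
    base = dict(max_epochs=2, patience=2, seed=0, batch_size=16, val_split=0.1,
                learning_rate=2e-3)
    base.update(kw)
    return ut.TrainingConfig(**base)


class TestEncodeDecode:
    def test_inference_deterministic(self, tiny_arch, tiny_patches):
        m = ut.AutoencoderModel(16, arch=tiny_arch, seed=0)
        z1 = m.encode(tiny_patches[0])
        z2 = m.encode(tiny_patches[0])
        assert np.array_equal(z1, z2)

    def test_batch_encode_matches_single(self, tiny_arch, tiny_patches):
        m = ut.AutoencoderModel(8, arch=tiny_arch, seed=1)
        batch = np.stack([p.data for p in tiny_patches[:5]])
        zb = m.encode(batch)
        for i in range(5):
            np.testing.assert_allclose(zb[i], m.encode(tiny_patches[i]), atol=1e-5)

    @pytest.mark.parametrize("k", swae.LATENT_SIZES)
    def test_latent_length_across_size_sweep(self, k, tiny_arch, tiny_patches):
        m = ut.AutoencoderModel(k, arch=tiny_arch, seed=0)
        z = m.encode(tiny_patches[0])
        assert z.shape == (k,)
        assert np.all(np.isfinite(z))

    def test_decode_shape_and_roundtrip_shape(self, tiny_arch, tiny_patches):
        m = ut.AutoencoderModel(8, arch=tiny_arch, seed=0)
        rec = m.reconstruct(tiny_patches[0].data)
        assert rec.shape == (24, 24, 24)
        assert np.all(np.isfinite(rec))

    def test_decode_dimension_mismatch(self, tiny_arch):
        m = ut.AutoencoderModel(8, arch=tiny_arch, seed=0)
        with pytest.raises(ValueError):
            m.decode(np.zeros(9))

    def test_encode_shape_mismatch(self, tiny_arch):
        m = ut.AutoencoderModel(8, arch=tiny_arch, seed=0)
        with pytest.raises(ValueError):
            m.encode(np.zeros((10, 10, 10)))


class TestSlicedWasserstein:
    def test_identical_sets_zero(self):
        z = np.random.default_rng(0).normal(size=(20, 5))
        assert sliced_wasserstein(z, z.copy(), 32, seed=1) == 0.0

    def test_two_point_one_dimensional(self):
        assert sliced_wasserstein([[0.0]], [[1.0]], 16, seed=0) == pytest.approx(1.0)

    def test_symmetry_under_shared_seed(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(30, 4)), rng.normal(size=(30, 4))
        assert sliced_wasserstein(a, b, 64, seed=9) == pytest.approx(
            sliced_wasserstein(b, a, 64, seed=9))

    def test_nonnegative(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
            assert sliced_wasserstein(a, b, 16, seed=0) >= 0.0

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sliced_wasserstein(np.zeros((3, 2)), np.zeros((4, 2)))

    def test_ball_prior_inside_radius(self):
        s = sample_ball_prior(500, 6, radius=2.0, rng=np.random.default_rng(0))
        norms = np.linalg.norm(s, axis=1)
        assert norms.max() <= 2.0 + 1e-6
        assert norms.min() > 0.0


class TestLoss:
    def test_components_recombine(self, tiny_arch, tiny_patches):
        m = ut.AutoencoderModel(8, arch=tiny_arch, seed=0)
        cfg = quick_config(alpha=0.7, beta=2.0)
        total, mse, sw = swae.loss(m, tiny_patches[:8], cfg, seed=5)
        assert total == pytest.approx(0.7 * mse + 2.0 * sw)
        assert mse >= 0 and sw >= 0

    def test_beta_zero_isolates_reconstruction(self, tiny_arch, tiny_patches):
        m = ut.AutoencoderModel(8, arch=tiny_arch, seed=0)
        total, mse, sw = swae.loss(m, tiny_patches[:4], quick_config(beta=0.0), seed=0)
        assert sw == 0.0
        assert total == pytest.approx(mse)

    def test_empty_batch_rejected(self, tiny_arch):
        m = ut.AutoencoderModel(8, arch=tiny_arch, seed=0)
        with pytest.raises(ValueError):
            swae.loss(m, [], quick_config(), seed=0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ut.TrainingConfig(alpha=0.0, beta=0.0).validate()
        with pytest.raises(ValueError):
            ut.TrainingConfig(val_split=1.5).validate()


class TestTrain:
    def test_training_reduces_loss(self, tiny_arch, tiny_patches):
        cfg = quick_config(max_epochs=4, beta=0.0)
        trained = swae.train(tiny_patches, 8, cfg, arch=tiny_arch)
        fresh = ut.AutoencoderModel(8, arch=tiny_arch, seed=cfg.seed)
        fresh.input_mean = trained.input_mean
        fresh.input_scale = trained.input_scale
        l_fresh, *_ = swae.loss(fresh, tiny_patches, cfg, seed=1)
        l_trained, *_ = swae.loss(trained, tiny_patches, cfg, seed=1)
        assert l_trained < l_fresh

    def test_early_stopping_contract(self, tiny_arch, tiny_patches):
        # zero learning rate -> validation never improves -> stop at patience+1
        cfg = quick_config(max_epochs=50, patience=2, learning_rate=0.0)
        m = swae.train(tiny_patches[:8], 8, cfg, arch=tiny_arch)
        assert m.training_meta["epochs_run"] == 3
        assert m.training_meta["best_epoch"] == 0

    def test_reproducible_under_seed(self, tiny_arch, tiny_patches):
        cfg = quick_config(max_epochs=2)
        m1 = swae.train(tiny_patches[:32], 8, cfg, arch=tiny_arch)
        m2 = swae.train(tiny_patches[:32], 8, cfg, arch=tiny_arch)
        for a, b in zip(m1.encoder.params() + m1.decoder.params(),
                        m2.encoder.params() + m2.decoder.params()):
            assert np.array_equal(a, b)

    def test_too_few_patches(self, tiny_arch):
        with pytest.raises(ValueError):
            swae.train([], 8, quick_config(), arch=tiny_arch)


@pytest.fixture(scope="module")
def base_model(tiny_arch, tiny_patches):
    return swae.train(tiny_patches[:32], 8, quick_config(), arch=tiny_arch)


class TestFinetune:
    def test_convolutions_bit_identical(self, base_model, tiny_patches):
        tuned = swae.finetune(base_model, tiny_patches[32:], quick_config(seed=3))
        for before, after in zip(base_model.conv_layers(), tuned.conv_layers()):
            assert np.array_equal(before.W, after.W)
            assert np.array_equal(before.b, after.b)
        changed = any(
            not np.array_equal(b.W, a.W)
            for b, a in zip(base_model.fc_layers(), tuned.fc_layers())
        )
        assert changed
        assert tuned.regime == "generalized_finetuned"

    def test_zero_epochs_is_noop(self, base_model, tiny_patches):
        tuned = swae.finetune(base_model, tiny_patches[32:], quick_config(max_epochs=0))
        for a, b in zip(base_model.encoder.params() + base_model.decoder.params(),
                        tuned.encoder.params() + tuned.decoder.params()):
            assert np.array_equal(a, b)
        assert tuned.regime == base_model.regime

    def test_untrained_model_rejected(self, tiny_arch, tiny_patches):
        fresh = ut.AutoencoderModel(8, arch=tiny_arch, seed=0)
        with pytest.raises(ValueError):
            swae.finetune(fresh, tiny_patches, quick_config())

    def test_subsample_capped(self, base_model, tiny_patches):
        tuned = swae.finetune(base_model, tiny_patches, quick_config(seed=1),
                              max_patches=10)
        assert tuned.training_meta["n_patches"] == 10


class TestRegimes:
    def test_leave_one_out_bookkeeping(self, tiny_arch, tiny_patches):
        subjects = [tiny_patches[:20], tiny_patches[20:40], tiny_patches[40:60]]
        cfg = quick_config(max_epochs=1)
        fams = swae.build_regime_models(subjects, 8, cfg, arch=tiny_arch,
                                        finetune_max_patches=15)
        assert set(fams) == set(swae.REGIMES)
        for i in range(3):
            assert fams["individual"][i].training_meta["n_patches"] == 20
            assert fams["generalized"][i].training_meta["n_patches"] == 40
            assert fams["generalized_finetuned"][i].training_meta["n_patches"] == 15
            assert fams["individual"][i].regime == "individual"
            assert fams["generalized"][i].regime == "generalized"
            assert fams["generalized_finetuned"][i].regime == "generalized_finetuned"

    def test_single_subject_rejected(self, tiny_arch, tiny_patches):
        with pytest.raises(ValueError):
            swae.build_regime_models([tiny_patches], 8, quick_config(), arch=tiny_arch)


class TestCheckpoint:
    def test_roundtrip_preserves_model(self, tiny_arch, tiny_patches, tmp_path):
        m = swae.train(tiny_patches[:32], 16, quick_config(), arch=tiny_arch)
        path = tmp_path / "model.npz"
        m.save(path)
        back = ut.AutoencoderModel.load(path)
        assert back.k == 16
        assert back.regime == m.regime
        assert back.training_meta == m.training_meta
        assert back.input_mean == m.input_mean and back.input_scale == m.input_scale
        np.testing.assert_array_equal(back.encode(tiny_patches[0]),
                                      m.encode(tiny_patches[0]))
        assert (tmp_path / "model.json").is_file()
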