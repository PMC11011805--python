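"""Adversarial autoencoder: contracts, oracles and training behaviour."""

import numpy as np
import pytest

from latexpl import (AAEConfig, AdversarialAutoencoder, corrupt,
                     generate_dataset, minibatch_similarity,
                     reconstruction_rmse)
from latexpl.synthetic import LabeledImageSet


class TestConfig:
    def test_non_doubling_stages_rejected(self):
        with pytest.raises(ValueError):
            AAEConfig(stage_resolutions=(7, 15)).validate()

    def test_disc_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            AAEConfig(stage_resolutions=(7, 14),
                      disc_widths=(100,)).validate()

    def test_default_widths_span_500_to_3000(self):
        w = AAEConfig().resolved_disc_widths()
        assert w[0] == 500 and w[-1] == 3000 and len(w) == 6

    def test_json_roundtrip(self):
        cfg = AAEConfig(latent_dim=32, stage_resolutions=(7, 14),
                        disc_widths=(64, 96))
        assert AAEConfig.from_json(cfg.to_json()) == cfg


class TestCorrupt:
    def test_sigma_zero_is_identity(self, rng):
        x = rng.random((8, 8, 3))
        np.testing.assert_array_equal(corrupt(x, 0.0, 1), x)

    def test_deterministic_under_seed(self, rng):
        x = rng.random((8, 8, 3))
        np.testing.assert_array_equal(corrupt(x, 0.1, 5), corrupt(x, 0.1, 5))

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            corrupt(np.zeros((4, 4, 3)), -0.1, 0)

    def test_noise_moments(self):
        # on a mid-grey image no clipping occurs, so the sample std of
        # the added field must match sigma
        x = np.full((224, 224, 3), 0.5)
        noise = corrupt(x, 0.1, seed=3) - x
        assert abs(noise.std() - 0.1) < 0.005
        assert abs(noise.mean()) < 0.005


class TestMinibatchSimilarity:
    def test_identical_rows_give_batch_size(self, rng):
        m, f, B, C = 6, 5, 3, 2
        F = np.tile(rng.normal(0, 1, (1, f)), (m, 1))
        T = rng.normal(0, 1, (f, B, C))
        np.testing.assert_allclose(minibatch_similarity(F, T),
                                   np.full((m, B), float(m)), atol=1e-12)

    def test_single_row_gives_one(self, rng):
        F = rng.normal(0, 1, (1, 4))
        T = rng.normal(0, 1, (4, 2, 3))
        np.testing.assert_allclose(minibatch_similarity(F, T),
                                   np.ones((1, 2)), atol=1e-12)

    @pytest.mark.parametrize("m,f,B,C", [(3, 4, 2, 2), (8, 6, 4, 4),
                                         (5, 3, 1, 4)])
    def test_matches_double_loop_oracle(self, rng, m, f, B, C):
        F = rng.normal(0, 1, (m, f))
        T = rng.normal(0, 1, (f, B, C))
        M = np.stack([(F[i] @ T.reshape(f, B * C)).reshape(B, C)
                      for i in range(m)])
        want = np.zeros((m, B))
        for i in range(m):
            for b in range(B):
                for j in range(m):
                    want[i, b] += np.exp(-np.abs(M[i, b] - M[j, b]).sum())
        np.testing.assert_allclose(minibatch_similarity(F, T), want,
                                   atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            minibatch_similarity(rng.normal(0, 1, (3, 4)),
                                 rng.normal(0, 1, (5, 2, 2)))


@pytest.fixture(scope="module")
def tiny_model():
    """Untrained single-stage model for contract checks."""
    m = AdversarialAutoencoder(
        latent_dim=8, stage_resolutions=(7,), disc_widths=(16,),
        mb_kernels=4, mb_dims=2, random_state=0)
    m._init_stage0(np.random.default_rng(0))
    return m


class TestModelContracts:
    def test_encode_shape_and_determinism(self, tiny_model, rng):
        x = rng.random((7, 7, 3))
        z1, z2 = tiny_model.encode(x), tiny_model.encode(x)
        assert z1.shape == (8,) and np.isfinite(z1).all()
        np.testing.assert_array_equal(z1, z2)

    def test_encode_rejects_wrong_resolution(self, tiny_model, rng):
        with pytest.raises(ValueError):
            tiny_model.encode(rng.random((14, 14, 3)))

    def test_decode_shape_range_determinism(self, tiny_model, rng):
        z = rng.normal(0, 1, 8)
        x1, x2 = tiny_model.decode(z), tiny_model.decode(z)
        assert x1.shape == (7, 7, 3)
        assert x1.min() >= 0 and x1.max() <= 1
        np.testing.assert_array_equal(x1, x2)

    def test_decode_rejects_wrong_length(self, tiny_model, rng):
        with pytest.raises(ValueError):
            tiny_model.decode(rng.normal(0, 1, 9))

    def test_discriminate_range_and_empty_batch(self, tiny_model, rng):
        scores = tiny_model.discriminate(rng.normal(0, 5, (10, 8)))
        assert scores.shape == (10,)
        assert (scores >= 0).all() and (scores <= 1).all()
        with pytest.raises(ValueError):
            tiny_model.discriminate(np.empty((0, 8)))

    def test_batch_permutation_equivariance_without_mb(self, rng):
        # B=0 ablation: scores are per-row, so permuting rows permutes
        # scores identically
        m = AdversarialAutoencoder(
            latent_dim=8, stage_resolutions=(7,), disc_widths=(16,),
            mb_kernels=0, random_state=0)
        m._init_stage0(np.random.default_rng(0))
        Z = rng.normal(0, 1, (6, 8))
        perm = rng.permutation(6)
        np.testing.assert_allclose(m.discriminate(Z)[perm],
                                   m.discriminate(Z[perm]), atol=1e-12)

    def test_minibatch_features_couple_batch_members(self, tiny_model, rng):
        # 8 identical codes scored together differ from the same codes
        # scored in a mixed batch — the B>0 layer sees batch context
        z = rng.normal(0, 1, 8)
        pure = np.tile(z, (8, 1))
        mixed = np.vstack([z[None], rng.normal(0, 1, (7, 8))])
        s_pure = tiny_model.discriminate(pure)[0]
        s_mixed = tiny_model.discriminate(mixed)[0]
        assert s_pure != pytest.approx(s_mixed, abs=1e-9)

    def test_sklearn_transform_surface(self, tiny_model, rng):
        X = rng.random((4, 7, 7, 3))
        Z = tiny_model.transform(X)
        assert Z.shape == (4, 8)
        assert tiny_model.inverse_transform(Z).shape == (4, 7, 7, 3)
        params = tiny_model.get_params()
        assert params["latent_dim"] == 8


class TestGrowth:
    def test_weight_transfer_preserves_trunk(self):
        m = AdversarialAutoencoder(
            latent_dim=8, stage_resolutions=(7, 14), disc_widths=(16, 24),
            mb_kernels=4, mb_dims=2, random_state=3)
        rng = np.random.default_rng(3)
        m._init_stage0(rng)
        enc_trunk = [(l, {k: v.copy() for k, v in l.params.items()})
                     for l in m.encoder_.layers[2:]]
        dec_trunk = [(l, {k: v.copy() for k, v in l.params.items()})
                     for l in m.decoder_.layers[:-2]]
        m.grow(rng)
        for layer, saved in enc_trunk + dec_trunk:
            assert layer in (m.encoder_.layers + m.decoder_.layers)
            for k, v in saved.items():
                np.testing.assert_array_equal(layer.params[k], v)

    def test_widened_discriminator_preserves_function(self):
        m = AdversarialAutoencoder(
            latent_dim=8, stage_resolutions=(7, 14), disc_widths=(16, 24),
            mb_kernels=4, mb_dims=2, random_state=3)
        rng = np.random.default_rng(3)
        m._init_stage0(rng)
        Z = np.random.default_rng(9).normal(0, 1, (10, 8))
        before = m.discriminate(Z)
        m._widen_discriminator(24, rng)
        np.testing.assert_allclose(m.discriminate(Z), before, atol=1e-10)


class TestRmse:
    def test_zero_and_extreme_cases(self):
        class Identity:
            def encode(self, X):
                return X.reshape(len(X), -1)

            def decode(self, Z):
                return Z.reshape(len(Z), 4, 4, 3)

        ones = LabeledImageSet(np.ones((3, 4, 4, 3)), np.zeros(3, dtype=int))
        overall, per = reconstruction_rmse(Identity(), ones)
        assert overall == 0.0 and per[0] == 0.0

        class AllZero(Identity):
            def decode(self, Z):
                return np.zeros((len(Z), 4, 4, 3))

        overall, _ = reconstruction_rmse(AllZero(), ones)
        assert overall == 1.0

    def test_matches_elementwise_oracle(self, rng):
        imgs = rng.random((5, 4, 4, 3))
        recon = rng.random((5, 4, 4, 3))

        class Stub:
            def encode(self, X):
                return np.arange(len(X))

            def decode(self, Z):
                return recon[np.asarray(Z, dtype=int)]

        data = LabeledImageSet(imgs, np.array([0, 0, 1, 1, 2]))
        overall, per = reconstruction_rmse(Stub(), data)
        want = np.sqrt(np.mean([(imgs[i] - recon[i]) ** 2
                                for i in range(5)]))
        assert overall == pytest.approx(want, abs=1e-10)
        want1 = np.sqrt(((imgs[2:4] - recon[2:4]) ** 2).mean())
        assert per[1] == pytest.approx(want1, abs=1e-10)

    def test_empty_rejected(self, tiny_model):
        empty = LabeledImageSet(np.empty((0, 7, 7, 3)),
                                np.empty(0, dtype=int))
        with pytest.raises(ValueError):
            reconstruction_rmse(tiny_model, empty)


class TestTraining:
    def test_single_stage_loss_decreases(self):
        # degenerate 1-stage schedule = plain denoising AAE
        data = generate_dataset(34, 3, 7, seed=5)
        model = AdversarialAutoencoder(
            latent_dim=16, stage_resolutions=(7,), disc_widths=(32,),
            epochs_per_stage=5, mb_kernels=4, mb_dims=2, random_state=1)
        model.fit(data.images)
        recon = [r["recon_loss"] for r in model.training_log_]
        assert recon[-1] < recon[0]

    def test_trained_model_beats_random_codes(self, desk_model, heldout):
        # autoencoding must beat decoding random prior draws
        X = heldout.images[:50]
        recon = desk_model.decode(desk_model.encode(X))
        rng = np.random.default_rng(3)
        rand = desk_model.decode(desk_model.sample_prior(50, rng))
        rmse_model = np.sqrt(((recon - X) ** 2).mean())
        rmse_rand = np.sqrt(((rand - X) ** 2).mean())
        assert rmse_model < rmse_rand

    def test_checkpoint_roundtrip(self, desk_model, tmp_path, rng):
        path = tmp_path / "model.npz"
        desk_model.save(path)
        loaded = AdversarialAutoencoder.load(path)
        x = rng.random((28, 28, 3))
        np.testing.assert_allclose(loaded.encode(x), desk_model.encode(x),
                                   atol=1e-12)
        z = rng.normal(0, 1, 32)
        np.testing.assert_allclose(loaded.decode(z), desk_model.decode(z),
                                   atol=1e-12)
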