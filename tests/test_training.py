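"""Adversarial step, label swapping, pretraining, transfer, HS training."""

import numpy as np
import pytest

from hsigan import gan_core as gc, nn, training as tr
from hsigan import synthetic_data as sd


class TestSwapLabels:
    def test_zero_fraction_identity(self):
        t = np.array([1.0, 0.0, 0.9, 0.1])
        np.testing.assert_array_equal(tr.swap_labels(t, 0.0), t)

    def test_binomial_flip_rate(self):
        t = np.ones(100_000)
        out = tr.swap_labels(t, 0.05, np.random.default_rng(0))
        flipped = int((out != t).sum())
        assert abs(flipped - 5000) < 3 * np.sqrt(100_000 * 0.05 * 0.95)

    def test_deterministic_under_rng_state(self):
        t = np.random.default_rng(1).random(1000)
        a = tr.swap_labels(t, 0.1, np.random.default_rng(2))
        b = tr.swap_labels(t, 0.1, np.random.default_rng(2))
        np.testing.assert_array_equal(a, b)

    def test_flip_maps_between_class_ranges(self):
        t = np.full(2000, 0.85)
        out = tr.swap_labels(t, 0.5 - 1e-9, np.random.default_rng(3))
        flipped = out[out != 0.85]
        assert len(flipped) > 0 and np.allclose(flipped, 0.15)


def _tiny_pair(conditional=False, seed=0):
    gs = gc.GeneratorSpec(latent_dim=8, out_height=8, out_width=8,
                          out_channels=3, base_channels=16,
                          conditional=conditional)
    ds = gc.DiscriminatorSpec(in_height=8, in_width=8, in_channels=3,
                              base_channels=8, conditional=conditional)
    return gc.build_generator(gs, seed), gc.build_discriminator(ds, seed + 1)


class TestAdversarialStep:
    def test_parameters_move(self):
        G, D = _tiny_pair()
        g0 = {k: v.copy() for k, v in G.params().items()}
        d0 = {k: v.copy() for k, v in D.params().items()}
        cfg = tr.TrainConfig.hs_cgan(seed=0)
        real = np.random.default_rng(0).uniform(-1, 1, (4, 3, 8, 8))
        tr.adversarial_step(G, D, real, cfg, np.random.default_rng(1))
        assert any(not np.array_equal(v, g0[k]) for k, v in G.params().items()
                   if not k.endswith(("running_mean", "running_var")))
        assert any(not np.array_equal(v, d0[k]) for k, v in D.params().items()
                   if not k.endswith(("running_mean", "running_var")))

    def test_zero_learning_rate_freezes_parameters(self):
        G, D = _tiny_pair()
        g0 = {k: v.copy() for k, v in G.params().items()}
        cfg = tr.TrainConfig.hs_cgan(lr_g=0.0, lr_d=0.0, seed=0)
        real = np.random.default_rng(0).uniform(-1, 1, (4, 3, 8, 8))
        ld, lg = tr.adversarial_step(G, D, real, cfg, np.random.default_rng(1))
        assert np.isfinite(ld) and np.isfinite(lg)
        for k, v in G.params().items():
            if k.endswith(("running_mean", "running_var")):
                continue  # batch-norm statistics still track activations
            np.testing.assert_array_equal(v, g0[k])

    def test_untrained_discriminator_loss_near_random_guessing(self):
        """At D ~ 0.5 the real+fake BCE pair sits near -2 ln(0.5)."""

        class FlatD:
            spec = gc.DiscriminatorSpec(in_height=8, in_width=8, in_channels=3,
                                        base_channels=8)

            def forward(self, x, labels=None, train=True):
                return np.full(x.shape[0], 0.5)

            def backward(self, grad):
                return np.zeros((len(grad), 3, 8, 8))

            def params(self):
                return {}

            def grads(self):
                return {}

        G, _ = _tiny_pair()
        cfg = tr.TrainConfig.hs_cgan(target_smoothing=False,
                                     label_swap_fraction=0.0, seed=0)
        real = np.zeros((6, 3, 8, 8))
        ld, _ = tr.adversarial_step(G, FlatD(), real, cfg, np.random.default_rng(2))
        assert ld == pytest.approx(-2 * np.log(0.5), rel=1e-9)

    def test_reduces_to_textbook_update_on_toy_models(self):
        """With smoothing and swapping off, the step equals the hand-derived
        DCGAN update (BCE discriminator, non-saturating generator) on
        one-parameter linear models, followed by a textbook Adam step."""

        class ToyG:
            spec = gc.GeneratorSpec(latent_dim=1, out_height=8, out_width=8,
                                    out_channels=1, base_channels=16)

            def __init__(self):
                self.a = np.array([0.5])
                self.da = np.zeros(1)

            def forward(self, z, labels=None, train=True):
                self._z = z[:, 0]
                return (self.a * z)[:, :, None, None] * np.ones((1, 1, 8, 8))

            def backward(self, grad):
                # d out / d a = z broadcast over the 8x8 plane
                self.da = np.array([np.sum(grad.sum(axis=(1, 2, 3)) * self._z)])

            def params(self):
                return {"a": self.a}

            def grads(self):
                return {"a": self.da}

        class ToyD:
            spec = gc.DiscriminatorSpec(in_height=8, in_width=8, in_channels=1,
                                        base_channels=8)

            def __init__(self):
                self.b = np.array([0.25])
                self.db = np.zeros(1)

            def forward(self, x, labels=None, train=True):
                self._m = x.mean(axis=(1, 2, 3))
                self._p = 1 / (1 + np.exp(-self.b * self._m))
                return self._p

            def backward(self, grad):
                s = grad * self._p * (1 - self._p)
                self.db = np.array([np.sum(s * self._m)])
                return (s * self.b)[:, None, None, None] * np.ones((1, 1, 8, 8)) / 64

            def params(self):
                return {"b": self.b}

            def grads(self):
                return {"b": self.db}

        G, D = ToyG(), ToyD()
        a0, b0 = G.a.copy(), D.b.copy()
        cfg = tr.TrainConfig.hs_cgan(target_smoothing=False,
                                     label_swap_fraction=0.0, l2_coeff=0.0,
                                     seed=0)
        real = np.full((4, 1, 8, 8), 0.3)
        rng_seed = 123
        tr.adversarial_step(G, D, real, cfg, np.random.default_rng(rng_seed))

        # ---- independent oracle ----------------------------------------
        rng = np.random.default_rng(rng_seed)
        z1 = rng.standard_normal((4, 1))[:, 0]
        z2 = rng.standard_normal((4, 1))[:, 0]
        sig = lambda v: 1 / (1 + np.exp(-v))
        # D loss: mean BCE(p_real, 1) + mean BCE(p_fake, 0)
        m_real = np.full(4, 0.3)
        m_fake1 = a0[0] * z1
        p_real, p_fake = sig(b0[0] * m_real), sig(b0[0] * m_fake1)
        db = (np.sum((p_real - 1) * m_real) + np.sum(p_fake * m_fake1)) / 4

        def adam1(p, g, lr):
            m_hat, v_hat = g, g * g
            return p - lr * m_hat / (np.sqrt(v_hat) + 1e-8)

        b1 = adam1(b0[0], db, cfg.lr_d)
        # G loss: mean BCE(D(fake2), 1) with updated D
        m_fake2 = a0[0] * z2
        p2 = sig(b1 * m_fake2)
        da = np.sum((p2 - 1) * b1 * z2) / 4
        a1 = adam1(a0[0], da, cfg.lr_g)
        assert D.b[0] == pytest.approx(b1, rel=1e-10)
        assert G.a[0] == pytest.approx(a1, rel=1e-10)

    def test_ttur_update_magnitudes_scale_with_lr_ratio(self):
        """On a frozen batch, parameter-update size tracks the configured lr."""
        moves = {}
        for lr_g, lr_d in ((1e-4, 4e-4), (2e-4, 8e-4)):
            G, D = _tiny_pair(seed=3)
            g0 = {k: v.copy() for k, v in G.params().items()}
            d0 = {k: v.copy() for k, v in D.params().items()}
            cfg = tr.TrainConfig.hs_cgan(lr_g=lr_g, lr_d=lr_d, l2_coeff=0.0, seed=0)
            real = np.random.default_rng(0).uniform(-1, 1, (4, 3, 8, 8))
            tr.adversarial_step(G, D, real, cfg, np.random.default_rng(1))
            dg = np.max([np.abs(v - g0[k]).max() for k, v in G.params().items()
                         if k.endswith(".w")])
            dd = np.max([np.abs(v - d0[k]).max() for k, v in D.params().items()
                         if k.endswith(".w")])
            moves[lr_g] = (dg, dd)
        # Adam first-step size is ~lr, so doubling both rates doubles moves
        assert moves[2e-4][0] == pytest.approx(2 * moves[1e-4][0], rel=1e-3)
        assert moves[2e-4][1] == pytest.approx(2 * moves[1e-4][1], rel=1e-3)


class TestPretrainRGB:
    def _blob_folder(self, tmp_path, n=12):
        from PIL import Image

        rng = np.random.default_rng(0)
        for i in range(n):
            img = np.full((16, 16, 3), 200, dtype=np.uint8)
            cy, cx = rng.integers(4, 12, 2)
            yy, xx = np.mgrid[0:16, 0:16]
            img[(yy - cy) ** 2 + (xx - cx) ** 2 < 16] = [120, 60, 50]
            Image.fromarray(img).save(tmp_path / f"blob_{i}.png")
        return tmp_path

    def test_smoke_pretrain_and_checkpoint(self, tmp_path):
        folder = self._blob_folder(tmp_path)
        cfg = tr.TrainConfig.rgb_pretrain(epochs=2, batch_size=4, seed=0)
        gs = gc.GeneratorSpec(out_height=16, out_width=16, out_channels=3,
                              base_channels=16)
        ds = gc.DiscriminatorSpec(in_height=16, in_width=16, in_channels=3,
                                  base_channels=8)
        ckpt = tmp_path / "rgb.npz"
        tr.pretrain_rgb(folder, cfg, gs, ds, checkpoint_path=ckpt)
        G, _, meta = gc.load_checkpoint(ckpt)
        assert meta["phase"] == "rgb_pretrain"
        out = G.forward(gc.sample_latent(2, 100, 0), train=False)
        assert out.shape == (2, 3, 16, 16)
        assert np.abs(out).max() <= 1.0

    def test_phase_mismatch_rejected(self, tmp_path):
        cfg = tr.TrainConfig.hs_cgan(seed=0)
        with pytest.raises(ValueError):
            tr.pretrain_rgb(tmp_path, cfg)

    def test_empty_folder_rejected(self, tmp_path):
        cfg = tr.TrainConfig.rgb_pretrain(epochs=1, seed=0)
        with pytest.raises(ValueError):
            tr.pretrain_rgb(tmp_path, cfg)

    def test_deterministic_losses(self, tmp_path):
        folder = self._blob_folder(tmp_path)
        cfg = tr.TrainConfig.rgb_pretrain(epochs=2, batch_size=4, seed=9)
        gs = gc.GeneratorSpec(out_height=16, out_width=16, out_channels=3,
                              base_channels=16)
        ds = gc.DiscriminatorSpec(in_height=16, in_width=16, in_channels=3,
                                  base_channels=8)
        logs = []
        for _ in range(2):
            log = []
            tr.pretrain_rgb(folder, cfg, gs, ds, log=log)
            logs.append(log)
        assert logs[0] == logs[1]


class TestTransferWeights:
    def _pair(self):
        gs_rgb = gc.GeneratorSpec(out_height=16, out_width=16, out_channels=3,
                                  base_channels=16)
        ds_rgb = gc.DiscriminatorSpec(in_height=16, in_width=16, in_channels=3,
                                      base_channels=8)
        G = gc.build_generator(gs_rgb, 0)
        D = gc.build_discriminator(ds_rgb, 1)
        gs_hs = gc.GeneratorSpec(out_height=16, out_width=16, out_channels=12,
                                 base_channels=16)
        ds_hs = gc.DiscriminatorSpec(in_height=16, in_width=16, in_channels=12,
                                     base_channels=8)
        bm = tr.BandMap({"red": 8, "green": 4, "blue": 0})
        return G, D, gs_hs, ds_hs, bm

    def test_interior_layers_copied_verbatim(self):
        G, D, gs, ds, bm = self._pair()
        Gh, Dh = tr.transfer_weights(G, D, gs, ds, bm, rng_seed=7)
        g_src = [l for l in G.net.layers if l.params()]
        g_dst = [l for l in Gh.net.layers if l.params()]
        for s, d in zip(g_src[:-1], g_dst[:-1]):  # all but the output conv
            for k, v in s.params().items():
                np.testing.assert_array_equal(v, d.params()[k])

    def test_mapped_band_slices_equal_rgb_slices(self):
        G, D, gs, ds, bm = self._pair()
        Gh, Dh = tr.transfer_weights(G, D, gs, ds, bm, rng_seed=7)
        g_out_src = [l for l in G.net.layers if l.params()][-1]
        g_out_dst = [l for l in Gh.net.layers if l.params()][-1]
        for rgb_idx, band in enumerate([8, 4, 0]):
            np.testing.assert_array_equal(g_out_dst.w[:, band],
                                          g_out_src.w[:, rgb_idx])
        d_in_src = [l for l in D.net.layers if l.params()][0]
        d_in_dst = [l for l in Dh.net.layers if l.params()][0]
        for rgb_idx, band in enumerate([8, 4, 0]):
            np.testing.assert_array_equal(d_in_dst.w[:, band],
                                          d_in_src.w[:, rgb_idx])

    def test_seed_isolation_of_new_channels(self):
        G, D, gs, ds, bm = self._pair()
        Gh1, _ = tr.transfer_weights(G, D, gs, ds, bm, rng_seed=7)
        Gh2, _ = tr.transfer_weights(G, D, gs, ds, bm, rng_seed=8)
        out1 = [l for l in Gh1.net.layers if l.params()][-1]
        out2 = [l for l in Gh2.net.layers if l.params()][-1]
        mapped = [8, 4, 0]
        unmapped = [i for i in range(12) if i not in mapped]
        for band in mapped:
            np.testing.assert_array_equal(out1.w[:, band], out2.w[:, band])
        assert not np.array_equal(out1.w[:, unmapped], out2.w[:, unmapped])

    def test_spec_mismatch_rejected(self):
        G, D, gs, ds, bm = self._pair()
        bad = gc.GeneratorSpec(out_height=20, out_width=20, out_channels=12,
                               base_channels=16)
        with pytest.raises(ValueError):
            tr.transfer_weights(G, D, bad, ds, bm, rng_seed=0)

    def test_band_map_validation(self):
        with pytest.raises(ValueError):
            tr.BandMap({"red": 1, "green": 1, "blue": 2})
        with pytest.raises(ValueError):
            tr.BandMap({"red": 1, "blue": 2})


class TestTrainHS:
    def test_batch_size_two_step_count(self):
        params = sd.PhantomParams(height=8, width=8, bands=4, seed=2)
        cubes = sd.make_dataset(params, 3, 2)  # n = 5 -> ceil(5/2) = 3 steps
        gs = gc.GeneratorSpec(latent_dim=8, out_height=8, out_width=8,
                              out_channels=5, base_channels=16, conditional=True)
        ds = gc.DiscriminatorSpec(in_height=8, in_width=8, in_channels=5,
                                  base_channels=8, conditional=True)
        G = gc.build_generator(gs, 0)
        D = gc.build_discriminator(ds, 1)
        cfg = tr.TrainConfig.hs_cgan(epochs=2, fid_every=0, seed=0)
        logs = tr.train_hs(cubes, cfg, G, D)
        assert [e["steps"] for e in logs] == [3, 3]

    def test_unlabeled_cube_rejected_in_conditional_mode(self):
        params = sd.PhantomParams(height=8, width=8, bands=4, seed=2)
        cubes = sd.make_dataset(params, 2, 2)
        cubes[1].label = None
        gs = gc.GeneratorSpec(latent_dim=8, out_height=8, out_width=8,
                              out_channels=5, base_channels=16, conditional=True)
        ds = gc.DiscriminatorSpec(in_height=8, in_width=8, in_channels=5,
                                  base_channels=8, conditional=True)
        cfg = tr.TrainConfig.hs_cgan(epochs=1, seed=0)
        with pytest.raises(ValueError):
            tr.train_hs(cubes, cfg, gc.build_generator(gs, 0),
                        gc.build_discriminator(ds, 1))

    def test_reproducible_from_config_seed(self):
        params = sd.PhantomParams(height=8, width=8, bands=4, seed=2)
        cubes = sd.make_dataset(params, 3, 3)
        logs = []
        for _ in range(2):
            gs = gc.GeneratorSpec(latent_dim=8, out_height=8, out_width=8,
                                  out_channels=5, base_channels=16,
                                  conditional=True)
            ds = gc.DiscriminatorSpec(in_height=8, in_width=8, in_channels=5,
                                      base_channels=8, conditional=True)
            cfg = tr.TrainConfig.hs_cgan(epochs=2, fid_every=0, seed=4)
            logs.append(tr.train_hs(cubes, cfg, gc.build_generator(gs, 0),
                                    gc.build_discriminator(ds, 1)))
        assert logs[0] == logs[1]
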