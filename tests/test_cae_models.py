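"""Autoencoder architectures: shape contracts, parameter parity, latents,
reconstruction loss, and short-training behaviour."""

import numpy as np
import pytest

from hsiseg import (
    ArchitectureConfig,
    TrainConfig,
    build_cae,
    concat_latents,
    count_parameters,
    decode,
    encode,
    pretrain_cae,
    reconstruction_loss,
)
from hsiseg.cae_models import LatentSet
from hsiseg.patchwork import NormalizationRecord, PatchSet

ARCH_GRID = [
    ("uwu2d", 20, 100),
    ("uwu2d", 10, 24),
    ("generic2d", 20, 100),
    ("generic2d", 12, 16),
    ("generic3d", 20, 100),
    ("generic3d", 10, 40),
]


def _patchset(n, p, b, seed=0, constant=None):
    rng = np.random.default_rng(seed)
    if constant is not None:
        patches = np.full((n, p, p, b), constant, dtype=np.float32)
    else:
        patches = rng.random((n, p, p, b), dtype=np.float32)
    coords = np.zeros((n, 2), dtype=int)
    return PatchSet(patches, coords, p, p, (p, p, b),
                    norm=NormalizationRecord(1.0, True))


class TestBuild:
    @pytest.mark.parametrize("arch,p,b", ARCH_GRID)
    def test_shape_inverse(self, arch, p, b):
        """Encoder and decoder are exact shape inverses for every arch."""
        cfg = ArchitectureConfig(arch=arch, patch_size=p, bands=b, latent_total=20,
                                 branches=4, seed=1)
        cae = build_cae(cfg)
        x = np.random.default_rng(0).random((3, p, p, b), dtype=np.float32)
        z, xhat = cae.forward(x)
        assert z.shape == (3, 20)
        assert xhat.shape == x.shape
        assert np.isfinite(z).all() and np.isfinite(xhat).all()

    def test_uwu_branch_latents(self):
        cfg = ArchitectureConfig(arch="uwu2d", patch_size=20, bands=100,
                                 latent_total=100, branches=4)
        ls = encode(build_cae(cfg), np.zeros((20, 20, 100), dtype=np.float32))
        assert ls.n_branches == 4
        assert all(z.shape == (1, 25) for z in ls.per_branch)
        assert concat_latents(ls).shape == (1, 100)

    def test_generic2d_single_branch(self):
        cfg = ArchitectureConfig(arch="generic2d", patch_size=20, bands=100)
        ls = encode(build_cae(cfg), np.zeros((20, 20, 100), dtype=np.float32))
        assert ls.n_branches == 1
        assert concat_latents(ls).shape == (1, 100)

    def test_parameter_parity_uwu_vs_generic2d(self):
        """Filter budgets keep the 2-D architectures within 20% in size."""
        u = count_parameters(build_cae(ArchitectureConfig("uwu2d", 20, 100)))
        g = count_parameters(build_cae(ArchitectureConfig("generic2d", 20, 100)))
        assert 0.8 <= u / g <= 1.25

    def test_indivisible_latent_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ArchitectureConfig(arch="uwu2d", latent_total=100, branches=3)

    def test_branches_below_band_count(self):
        with pytest.raises(ValueError, match="branch"):
            ArchitectureConfig(arch="uwu2d", bands=4, branches=4, latent_total=8)


class TestEncodeDecode:
    @pytest.fixture(scope="class")
    def small_cae(self):
        return build_cae(
            ArchitectureConfig("uwu2d", patch_size=10, bands=12, latent_total=16,
                               branches=2, seed=5)
        )

    def test_zero_patch_finite(self, small_cae):
        ls = encode(small_cae, np.zeros((10, 10, 12), dtype=np.float32))
        assert np.isfinite(concat_latents(ls)).all()

    def test_deterministic(self, small_cae):
        x = np.random.default_rng(1).random((10, 10, 12), dtype=np.float32)
        a = concat_latents(encode(small_cae, x))
        b = concat_latents(encode(small_cae, x))
        np.testing.assert_array_equal(a, b)

    def test_decode_shape_and_finiteness(self, small_cae):
        ls = encode(small_cae, np.zeros((4, 10, 10, 12), dtype=np.float32))
        out = decode(small_cae, ls)
        assert out.shape == (4, 10, 10, 12)
        assert np.isfinite(out).all()

    def test_decode_from_concat_array(self, small_cae):
        z = np.random.default_rng(2).normal(size=(2, 16)).astype(np.float32)
        assert decode(small_cae, z).shape == (2, 10, 10, 12)

    def test_wrong_latent_length(self, small_cae):
        with pytest.raises(ValueError, match="latent length"):
            decode(small_cae, np.zeros((2, 7), dtype=np.float32))

    def test_shape_mismatch_rejected(self, small_cae):
        with pytest.raises(ValueError, match="patch shape"):
            encode(small_cae, np.zeros((9, 9, 12), dtype=np.float32))


class TestReconstructionLoss:
    def test_identity_zero(self):
        x = np.random.default_rng(0).random((3, 3, 2))
        assert reconstruction_loss(x, x) == 0.0

    def test_constant_offset(self):
        x = np.zeros((4, 4, 2))
        assert reconstruction_loss(x, np.ones_like(x)) == pytest.approx(1.0)

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(3)
        x, y = rng.random((3, 3, 2)), rng.random((3, 3, 2))
        brute = sum(
            (x[i, j, k] - y[i, j, k]) ** 2
            for i in range(3) for j in range(3) for k in range(2)
        ) / 18
        assert reconstruction_loss(x, y) == pytest.approx(brute, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))


class TestConcat:
    def test_ordered_concatenation(self):
        ls = LatentSet([np.array([[1.0, 2.0]]), np.array([[3.0, 4.0]])])
        np.testing.assert_array_equal(concat_latents(ls), [[1, 2, 3, 4]])

    def test_missing_branch(self):
        with pytest.raises(ValueError, match="branch"):
            concat_latents(LatentSet([]))


class TestTrainingBehaviour:
    def test_overfits_constant_patches(self):
        """Pretraining on identical constant patches memorises them."""
        cfg = ArchitectureConfig("uwu2d", patch_size=8, bands=6, latent_total=8,
                                 branches=2, seed=0)
        cae = build_cae(cfg)
        ps = _patchset(10, 8, 6, constant=0.5)
        tc = TrainConfig(seed=0, fixed_pretrain_epochs=100, batch_size=5,
                         learning_rate=0.01, validation_fraction=0.2)
        cae, hist = pretrain_cae(cae, ps, tc)
        _, xhat = cae.forward(ps.patches)
        assert reconstruction_loss(ps.patches, xhat) < 1e-3
        assert hist["train_loss"][-1] < 1e-4

    def test_loss_decreases_in_moving_average(self):
        cfg = ArchitectureConfig("generic2d", patch_size=8, bands=6, latent_total=8, seed=1)
        cae = build_cae(cfg)
        ps = _patchset(30, 8, 6, seed=2)
        tc = TrainConfig(seed=1, fixed_pretrain_epochs=20, batch_size=10)
        _, hist = pretrain_cae(cae, ps, tc)
        losses = np.array(hist["train_loss"])
        smooth = np.convolve(losses, np.ones(5) / 5, mode="valid")
        assert smooth[-1] < smooth[0]

    def test_history_records_protocol(self):
        cfg = ArchitectureConfig("generic2d", patch_size=8, bands=6, latent_total=8)
        ps = _patchset(12, 8, 6)
        tc = TrainConfig(seed=0, fixed_pretrain_epochs=2, batch_size=58)
        _, hist = pretrain_cae(build_cae(cfg), ps, tc)
        assert hist["batch_size"] == 58
        assert hist["learning_rate"] == 0.001
        assert hist["optimizer"] == "adam"

    def test_trained_net_separates_two_classes(self):
        """Latents of two distinct constant-patch classes move apart."""
        cfg = ArchitectureConfig("uwu2d", patch_size=8, bands=6, latent_total=8,
                                 branches=2, seed=3)
        cae = build_cae(cfg)
        a = np.full((10, 8, 8, 6), 0.2, dtype=np.float32)
        b = np.full((10, 8, 8, 6), 0.9, dtype=np.float32)
        patches = np.concatenate([a, b])
        ps = PatchSet(patches, np.zeros((20, 2), dtype=int), 8, 8, (8, 8, 6),
                      norm=NormalizationRecord(1.0, True))
        tc = TrainConfig(seed=3, fixed_pretrain_epochs=30, batch_size=10,
                         validation_fraction=0.2)
        cae, _ = pretrain_cae(cae, ps, tc)
        za = cae.encode_array(a)
        zb = cae.encode_array(b)
        gap = np.linalg.norm(za.mean(0) - zb.mean(0))
        assert gap > 0

    def test_branch_latents_drive_reconstruction(self):
        """Zeroing one branch latent changes the decoded patch (no dead branches)."""
        cfg = ArchitectureConfig("uwu2d", patch_size=8, bands=6, latent_total=8,
                                 branches=2, seed=4)
        cae = build_cae(cfg)
        rng = np.random.default_rng(0)
        ps = _patchset(16, 8, 6, seed=5)
        tc = TrainConfig(seed=4, fixed_pretrain_epochs=20, batch_size=8,
                         validation_fraction=0.2)
        cae, _ = pretrain_cae(cae, ps, tc)
        z = cae.encode_array(ps.patches[:1])
        base = decode(cae, z)
        changed = 0
        for m in range(2):
            zz = z.copy()
            zz[:, m * 4 : (m + 1) * 4] = 0
            if not np.allclose(decode(cae, zz), base):
                changed += 1
        assert changed == 2
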