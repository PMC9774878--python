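"""Clustering head: soft assignments, target sharpening, KL loss and its
gradients, centre initialisation, and the joint training loop."""

import numpy as np
import pytest

from hsiseg import (
    ArchitectureConfig,
    ClusterState,
    TrainConfig,
    build_cae,
    cae_kmeans,
    clustering_loss,
    init_centers,
    pretrain_cae,
    soft_assign,
    target_distribution,
    train_end_to_end,
)
from hsiseg.deep_cluster import clustering_gradients
from hsiseg.metrics import ars
from hsiseg.patchwork import NormalizationRecord, PatchSet


class TestInitCenters:
    def test_single_center_is_mean(self):
        z = np.random.default_rng(0).normal(size=(20, 4))
        cs = init_centers(z, 1)
        np.testing.assert_allclose(cs.centers[0], z.mean(axis=0))

    def test_n_equals_k_points(self):
        z = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        cs = init_centers(z, 3, seed=0)
        got = {tuple(c) for c in cs.centers}
        assert got == {(0, 0), (10, 0), (0, 10)}

    def test_two_blob_recovery(self):
        """Centres land near the true means of well-separated blobs."""
        rng = np.random.default_rng(1)
        n, sigma = 200, 0.5
        a = rng.normal(0, sigma, (n, 3))
        b = rng.normal(8, sigma, (n, 3))
        cs = init_centers(np.vstack([a, b]), 2, seed=1)
        tol = 3 * sigma / np.sqrt(n)
        dists = np.sort(
            [min(np.linalg.norm(c - 0.0), np.linalg.norm(c - 8.0)) for c in cs.centers]
        )
        assert (dists < 3 * tol * np.sqrt(3)).all()

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least"):
            init_centers(np.zeros((2, 3)), 5)

    def test_deterministic(self):
        z = np.random.default_rng(2).normal(size=(50, 4))
        a = init_centers(z, 3, seed=9).centers
        b = init_centers(z, 3, seed=9).centers
        np.testing.assert_array_equal(a, b)


class TestSoftAssign:
    def test_single_cluster_full_membership(self):
        q = soft_assign(np.random.default_rng(0).normal(size=(5, 2)),
                        ClusterState(np.zeros((1, 2))))
        np.testing.assert_array_equal(q, 1.0)

    def test_equidistant_symmetry(self):
        cs = ClusterState(np.array([[-1.0], [1.0]]))
        q = soft_assign(np.array([[0.0]]), cs)
        np.testing.assert_allclose(q, [[0.5, 0.5]])

    def test_student_t_formula_1d(self):
        """z=0, centres {0, 1}, alpha=1 -> unnormalised (1, 1/2) -> (2/3, 1/3)."""
        cs = ClusterState(np.array([[0.0], [1.0]]), alpha=1.0)
        q = soft_assign(np.array([[0.0]]), cs)
        np.testing.assert_allclose(q, [[2 / 3, 1 / 3]], atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        q = soft_assign(rng.normal(size=(40, 6)), ClusterState(rng.normal(size=(5, 6))))
        np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-9)
        assert (q >= 0).all()


class TestTargetDistribution:
    def test_one_hot_fixed_point(self):
        q = np.eye(3)[[0, 1, 2, 0]]
        np.testing.assert_allclose(target_distribution(q), q)

    def test_hand_worked_example(self):
        """f = (1.4, 0.6): p ~ [[0.873, 0.127], [0.491, 0.509]]."""
        q = np.array([[0.8, 0.2], [0.6, 0.4]])
        p = target_distribution(q)
        np.testing.assert_allclose(
            p, [[0.87272727, 0.12727273], [0.49090909, 0.50909091]], atol=1e-8
        )

    def test_uniform_invariant(self):
        q = np.full((6, 3), 1 / 3)
        np.testing.assert_allclose(target_distribution(q), q)

    def test_sharpens_entropy(self):
        rng = np.random.default_rng(4)
        q = rng.dirichlet(np.ones(4) * 2, size=100)
        p = target_distribution(q)

        def entropy(m):
            mm = np.where(m > 0, m, 1.0)
            return -(m * np.log(mm)).sum(axis=1)

        assert entropy(p).mean() <= entropy(q).mean()

    def test_dead_cluster_warning(self):
        q = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="zero soft count"):
            p = target_distribution(q)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)


class TestClusteringLoss:
    def test_zero_at_equality(self):
        q = np.random.default_rng(0).dirichlet(np.ones(3), size=5)
        assert clustering_loss(q, q) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_vs_uniform(self):
        p = np.array([[1.0, 0.0]])
        q = np.array([[0.5, 0.5]])
        assert clustering_loss(q, p) == pytest.approx(np.log(2))

    def test_non_negative_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.dirichlet(np.ones(4), size=6)
            q = rng.dirichlet(np.ones(4), size=6)
            assert clustering_loss(q, p) >= 0

    def test_matches_brute_force_double_sum(self):
        """Vectorised KL equals the element-wise double sum to 1e-10."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.dirichlet(np.ones(3), size=5)
            q = rng.dirichlet(np.ones(3), size=5)
            brute = np.mean(
                [
                    sum(
                        p[i, j] * (np.log(p[i, j]) - np.log(q[i, j]))
                        for j in range(3)
                        if p[i, j] > 0
                    )
                    for i in range(5)
                ]
            )
            assert abs(clustering_loss(q, p) - brute) < 1e-10

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=(6, 3))
        cs = ClusterState(rng.normal(size=(2, 3)))
        p = target_distribution(soft_assign(z, cs))
        dz, dmu = clustering_gradients(z, cs, p)
        eps = 1e-6

        def loss():
            return clustering_loss(soft_assign(z, cs), p)

        for arr, grad in ((z, dz), (cs.centers, dmu)):
            idx = (1, arr.shape[1] - 1)
            arr[idx] += eps
            fp = loss()
            arr[idx] -= 2 * eps
            fm = loss()
            arr[idx] += eps
            assert (fp - fm) / (2 * eps) == pytest.approx(grad[idx], rel=1e-4)


def _two_class_patchset(n_per=30, p=8, b=6, seed=0):
    """Spectrally distinct constant patch classes: trivially separable."""
    a = np.full((n_per, p, p, b), 0.15, dtype=np.float32)
    v = np.full((n_per, p, p, b), 0.85, dtype=np.float32)
    patches = np.concatenate([a, v])
    rng = np.random.default_rng(seed)
    patches += rng.normal(0, 0.01, patches.shape).astype(np.float32)
    truth = np.repeat([0, 1], n_per)
    ps = PatchSet(patches, np.zeros((2 * n_per, 2), dtype=int), p, p, (p, p, b),
                  norm=NormalizationRecord(1.0, True))
    return ps, truth


class TestJointTraining:
    @pytest.fixture(scope="class")
    def pretrained(self):
        ps, truth = _two_class_patchset()
        cfg = ArchitectureConfig("uwu2d", patch_size=8, bands=6, latent_total=8,
                                 branches=2, seed=0)
        tc = TrainConfig(seed=0, fixed_pretrain_epochs=30, batch_size=12,
                         validation_fraction=0.2)
        cae, _ = pretrain_cae(build_cae(cfg), ps, tc)
        return cae, ps, truth

    def test_cae_kmeans_separates_classes(self, pretrained):
        cae, ps, truth = pretrained
        labels = cae_kmeans(cae, ps, 2, seed=0)
        assert ars(labels, truth) == pytest.approx(1.0)

    def test_cae_kmeans_deterministic(self, pretrained):
        cae, ps, _ = pretrained
        a = cae_kmeans(cae, ps, 2, seed=3)
        b = cae_kmeans(cae, ps, 2, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_cae_kmeans_single_cluster(self, pretrained):
        cae, ps, _ = pretrained
        assert (cae_kmeans(cae, ps, 1) == 0).all()

    def test_end_to_end_recovers_partition_and_halts(self, pretrained):
        """Separable classes: exact recovery, and the <0.1%-change rule stops
        training before the epoch cap."""
        cae, ps, truth = pretrained
        tc = TrainConfig(seed=0, max_joint_epochs=50)
        tr = train_end_to_end(cae, ps, 2, tc)
        assert ars(tr.labels, truth) == pytest.approx(1.0)
        assert tr.stop_reason == "label_change_below_tol"
        assert tr.history["label_change"][-1] < tc.label_change_tol
        assert tr.history["epochs"] < 50

    def test_q_rows_stochastic_every_epoch(self, pretrained):
        cae, ps, _ = pretrained
        tc = TrainConfig(seed=1, max_joint_epochs=3, label_change_tol=1e-9)
        tr = train_end_to_end(cae, ps, 2, tc)
        np.testing.assert_allclose(tr.q.sum(axis=1), 1.0, atol=1e-9)
        p = target_distribution(tr.q)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_gamma_zero_reduces_to_reconstruction(self, pretrained):
        """With gamma = 0 the clustering loss cannot move the labels away
        from k-means of the evolving latents."""
        cae, ps, truth = pretrained
        tc = TrainConfig(seed=2, gamma=0.0, max_joint_epochs=2, label_change_tol=1e-9)
        tr = train_end_to_end(cae, ps, 2, tc)
        assert np.allclose(
            tr.history["total_loss"], tr.history["recon_loss"]
        )
        assert ars(tr.labels, truth) == pytest.approx(1.0)
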