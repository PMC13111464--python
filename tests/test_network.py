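"""Network building blocks: sampling/grouping, symmetric encoder, decoder,
gradient flow, training contracts."""

import numpy as np
import pytest

from phenopoint.cloud_core import PointCloud
from phenopoint.network import (Adam, NetworkConfig, SAEncoder, SALevelConfig,
                                TrainConfig, VGDSPointNet2, desk_preset,
                                fp_interpolate, load_checkpoint,
                                sa_group, sa_sample, save_checkpoint, train,
                                weighted_cross_entropy, _softmax)


def _tiny_config(sampler="vgds"):
    return NetworkConfig(
        sa_levels=(SALevelConfig(32, 0.1, 8, (16, 16), (16,)),
                   SALevelConfig(8, 0.2, 4, (16, 32), (32,))),
        fp_widths=((16, 16), (32, 16)),
        head_width=16, dropout=0.0, sampler=sampler)


def _toy_plant(rng, n=256):
    """Crude two-class cloud: a vertical rod (0) and a horizontal disc (2)."""
    rod = np.column_stack([rng.normal(0, 1, (n // 2, 2)),
                           rng.uniform(0, 60, (n // 2, 1))])
    disc = np.column_stack([rng.uniform(-30, 30, (n // 2, 2)),
                            rng.normal(40, 1, (n // 2, 1))])
    xyz = np.vstack([rod, disc])
    labels = np.r_[np.zeros(n // 2, int), np.full(n // 2, 2)]
    return xyz, labels


class TestSampleGroup:
    def test_identity_when_target_equals_n(self, rng):
        pts = rng.uniform(0, 1, (64, 3))
        out = sa_sample(pts, 64)
        assert len(out) == 64

    def test_single_centroid_inside_hull(self, rng):
        pts = rng.uniform(0, 10, (128, 3))
        c = sa_sample(pts, 1)
        assert np.all(c >= pts.min(axis=0) - 1e-9)
        assert np.all(c <= pts.max(axis=0) + 1e-9)

    def test_vgds_centroids_spread_better_than_random(self, rng):
        pts = rng.uniform(0, 1, (4096, 3))
        cents = sa_sample(pts, 512, "vgds", seed=0)
        rand = pts[rng.choice(4096, 512, replace=False)]

        def nn_spacing_cv(x):
            from scipy.spatial import cKDTree
            d, _ = cKDTree(x).query(x, k=2)
            d = d[:, 1]
            return d.std() / d.mean()

        assert nn_spacing_cv(cents) < nn_spacing_cv(rand)

    def test_group_relative_center_is_zero(self, rng):
        pts = rng.uniform(0, 1, (50, 3))
        groups, idx = sa_group(pts, None, pts[:5], radius=10.0, k=4)
        # each centroid is an input point, so its own relative coord is 0
        assert np.allclose(np.abs(groups).min(axis=1)[:, :3], 0.0)

    def test_whole_cloud_group_when_radius_spans(self, rng):
        pts = rng.uniform(0, 1, (20, 3))
        groups, idx = sa_group(pts, None, pts[:1], radius=10.0, k=20)
        assert sorted(idx[0].tolist()) == list(range(20))

    def test_no_cross_cluster_membership(self, rng):
        a = rng.normal(0, 1, (30, 3))
        b = rng.normal(100, 1, (30, 3))
        pts = np.vstack([a, b])
        groups, idx = sa_group(pts, None, np.array([[0.0, 0, 0],
                                                    [100.0, 100, 100]]),
                               radius=10.0, k=16)
        assert np.all(idx[0] < 30)
        assert np.all(idx[1] >= 30)


class TestEncoder:
    def test_permutation_invariance_exact(self, rng):
        enc = SAEncoder(3, (8, 16), (16,), rng)
        g = rng.normal(size=(5, 7, 3))
        out1 = enc.encode(g)
        perm = rng.permutation(7)
        out2 = enc.encode(g[:, perm, :])
        np.testing.assert_array_equal(out1, out2)

    def test_duplication_invariance(self, rng):
        enc = SAEncoder(3, (8, 16), (), rng)
        g = rng.normal(size=(4, 6, 3))
        g_dup = np.concatenate([g, g[:, :1, :]], axis=1)
        np.testing.assert_array_equal(enc.encode(g), enc.encode(g_dup))

    def test_singleton_neighborhood_is_gamma_h(self, rng):
        enc = SAEncoder(3, (8,), (8,), rng)
        x = rng.normal(size=(3, 1, 3))
        out = enc.encode(x)
        h = np.maximum(x.reshape(3, 3) @ enc.h.layers[0].W
                       + enc.h.layers[0].b, 0)
        expected = np.maximum(h @ enc.gamma.layers[0].W
                              + enc.gamma.layers[0].b, 0)
        np.testing.assert_allclose(out, expected)

    def test_gradient_matches_finite_differences(self, rng):
        """The hand-written backward pass agrees with numerical gradients."""
        enc = SAEncoder(3, (4, 5), (6,), rng)
        g = rng.normal(size=(3, 4, 3))
        target = rng.normal(size=(3, 6))

        def loss():
            return 0.5 * np.sum((enc.encode(g) - target) ** 2)

        base = enc.encode(g)
        enc.zero_grad()
        enc.backward(base - target)
        W = enc.h.layers[0].W
        gW = enc.h.layers[0].gW.copy()
        eps = 1e-6
        for idx in [(0, 0), (1, 2), (2, 3)]:
            W[idx] += eps
            up = loss()
            W[idx] -= 2 * eps
            down = loss()
            W[idx] += eps
            assert gW[idx] == pytest.approx((up - down) / (2 * eps), rel=1e-4,
                                            abs=1e-8)


class TestDecoder:
    def test_coincident_point_inherits_feature(self, rng):
        coarse = rng.uniform(0, 1, (5, 3))
        fine = np.vstack([coarse[2], rng.uniform(0, 1, (4, 3))])
        idx, w = fp_interpolate(fine, coarse, k=3)
        feats = rng.normal(size=(5, 7))
        out = (feats[idx] * w[..., None]).sum(axis=1)
        np.testing.assert_allclose(out[0], feats[2])

    def test_constant_features_interpolate_to_constant(self, rng):
        coarse = rng.uniform(0, 1, (6, 3))
        fine = rng.uniform(0, 1, (10, 3))
        idx, w = fp_interpolate(fine, coarse)
        feats = np.tile([1.5, -2.0], (6, 1))
        out = (feats[idx] * w[..., None]).sum(axis=1)
        np.testing.assert_allclose(out, np.tile([1.5, -2.0], (10, 1)))

    def test_midpoint_of_two_centroids_is_mean(self):
        coarse = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        fine = np.array([[1.0, 0, 0]])
        idx, w = fp_interpolate(fine, coarse, k=3)
        feats = np.array([[1.0], [3.0]])
        out = (feats[idx] * w[..., None]).sum(axis=1)
        assert out[0, 0] == pytest.approx(2.0)


class TestModelContracts:
    def test_shapes_decrease_across_levels(self, rng):
        model = VGDSPointNet2(_tiny_config(), seed=0)
        xyz = rng.uniform(0, 1, (128, 3))
        pyr = model.build_pyramid(xyz)
        counts = [len(x) for x in pyr["levels_xyz"]]
        assert counts == [128, 32, 8]
        logits = model.forward(pyr)
        assert logits.shape == (128, 3)

    def test_sampler_toggle_changes_no_shapes(self, rng):
        """Swapping VGDS for FPS in the sampling layer is a drop-in change:
        every downstream tensor keeps its shape."""
        xyz = rng.uniform(0, 1, (128, 3))
        shapes = {}
        for sampler in ("vgds", "fps"):
            model = VGDSPointNet2(_tiny_config(sampler), seed=0)
            pyr = model.build_pyramid(xyz)
            shapes[sampler] = ([x.shape for x in pyr["levels_xyz"]],
                               model.forward(pyr).shape)
        assert shapes["vgds"] == shapes["fps"]

    def test_loss_strictly_decreases_over_first_steps(self, rng):
        """Five Adam steps at lr 1e-4 on a fixed batch strictly cut the loss
        (3 seeds)."""
        for seed in range(3):
            r = np.random.default_rng(seed)
            xyz, labels = _toy_plant(r)
            model = VGDSPointNet2(_tiny_config(), seed=seed)
            pyr = model.build_pyramid(xyz)
            opt = Adam(model, 1e-4, 0.0)
            weights = np.ones(3)
            losses = []
            for _ in range(5):
                logits = model.forward(pyr)
                loss, dlog = weighted_cross_entropy(logits, labels, weights)
                losses.append(loss)
                model.zero_grad()
                model.backward(dlog)
                opt.step()
            logits = model.forward(pyr)
            losses.append(weighted_cross_entropy(logits, labels, weights)[0])
            assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_zero_lr_freezes_parameters(self, rng):
        xyz, labels = _toy_plant(rng)
        model = VGDSPointNet2(_tiny_config(), seed=0)
        before = [p.copy() for p, _ in model.params()]
        cfg = TrainConfig(batch_size=1, learning_rate=0.0, epochs=3,
                          patience=10, seed=0)
        hist = train(model, [(xyz, labels)], cfg)
        for b, (p, _) in zip(before, model.params()):
            np.testing.assert_array_equal(b, p)
        assert np.ptp(hist["loss"]) == pytest.approx(0.0, abs=1e-12)

    def test_early_stop_after_patience(self, rng):
        xyz, labels = _toy_plant(rng)
        model = VGDSPointNet2(_tiny_config(), seed=0)
        cfg = TrainConfig(batch_size=1, learning_rate=0.0, epochs=50,
                          patience=1, seed=0)
        hist = train(model, [(xyz, labels)], cfg)
        # constant validation mIoU: stop after the second evaluation
        assert len(hist["val_miou"]) == 2

    def test_empty_dataset_rejected(self):
        model = VGDSPointNet2(_tiny_config(), seed=0)
        with pytest.raises(ValueError):
            train(model, [], TrainConfig())

    def test_untrained_predict_rejected(self, rng):
        from phenopoint.network import predict
        model = VGDSPointNet2(_tiny_config(), seed=0)
        cloud = PointCloud(rng.uniform(0, 1, (64, 3)), np.zeros((64, 3)))
        with pytest.raises(ValueError):
            predict(model, cloud)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        xyz, labels = _toy_plant(rng)
        model = VGDSPointNet2(_tiny_config(), seed=0)
        cfg = TrainConfig(batch_size=1, learning_rate=1e-3, epochs=2,
                          patience=5, seed=0)
        hist = train(model, [(xyz, labels)], cfg)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path, hist)
        loaded, hist2 = load_checkpoint(path)
        pyr = model.build_pyramid(xyz)
        np.testing.assert_array_equal(model.forward(pyr),
                                      loaded.forward(loaded.build_pyramid(xyz)))
        assert hist2["loss"] == hist["loss"]

    def test_scores_sum_to_one_and_argmax_consistent(self, rng):
        from phenopoint.network import predict
        xyz, labels = _toy_plant(rng)
        model = VGDSPointNet2(_tiny_config(), seed=0)
        cfg = TrainConfig(batch_size=1, learning_rate=1e-3, epochs=2,
                          patience=5, seed=0)
        train(model, [(xyz, labels)], cfg)
        cloud = PointCloud(xyz, np.zeros((len(xyz), 3)))
        pred = predict(model, cloud, n_points=128)
        np.testing.assert_allclose(pred.scores.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(pred.scores.argmax(1), pred.labels)

    def test_translation_invariance_of_prediction(self, rng):
        from phenopoint.network import predict
        xyz, labels = _toy_plant(rng)
        model = VGDSPointNet2(_tiny_config(), seed=0)
        cfg = TrainConfig(batch_size=1, learning_rate=1e-3, epochs=3,
                          patience=5, seed=0)
        train(model, [(xyz, labels)], cfg)
        cloud = PointCloud(xyz, np.zeros((len(xyz), 3)))
        moved = PointCloud(xyz + [1000.0, -500.0, 250.0],
                           np.zeros((len(xyz), 3)))
        a = predict(model, cloud, n_points=128)
        b = predict(model, moved, n_points=128)
        assert np.mean(a.labels == b.labels) > 0.99

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(sa_levels=(SALevelConfig(8, 0.1),
                                     SALevelConfig(16, 0.1)),
                          fp_widths=((8,), (8,)))
        with pytest.raises(ValueError):
            TrainConfig(patience=0)
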