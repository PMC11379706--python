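import numpy as np
import pytest

from myth import _net
from myth.errors import ConfigurationError, ValidationError
from myth.model_core import (LabeledImage, PrototypeSet, TrainConfig,
                             build_model, classify, embed, embed_batch,
                             init_final_layer, loss, prototype_distances,
                             similarity_from_distance, train_local)

from conftest import TINY_SHAPE, random_image


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

class TestBuildModel:
    def test_paper_scale_counts(self):
        m = build_model((64, 64, 1), depth=128, per_class=10, n_classes=2)
        assert m.prototypes.m == 20
        assert m.prototypes.depth == 128

    def test_tiny_counts(self):
        m = build_model(TINY_SHAPE, depth=4, per_class=1, n_classes=2)
        assert m.prototypes.m == 2
        assert m.final_weights.shape == (2, 2)

    def test_seeded_determinism(self):
        a = build_model(TINY_SHAPE, depth=4, per_class=2, seed=5)
        b = build_model(TINY_SHAPE, depth=4, per_class=2, seed=5)
        assert np.array_equal(a.prototypes.vectors, b.prototypes.vectors)
        for k in a.conv_weights:
            assert np.array_equal(a.conv_weights[k], b.conv_weights[k])

    def test_unknown_backbone(self):
        with pytest.raises(ConfigurationError):
            build_model(TINY_SHAPE, backbone="resnet9000")

    def test_densenet_requires_torch(self):
        with pytest.raises(ConfigurationError, match="torch"):
            build_model(TINY_SHAPE, backbone="densenet")

    def test_prototypes_in_unit_cube(self):
        m = build_model(TINY_SHAPE, depth=8, per_class=3)
        assert m.prototypes.vectors.min() >= 0.0
        assert m.prototypes.vectors.max() <= 1.0


class TestInitFinalLayer:
    def test_two_prototypes(self):
        w = init_final_layer([0, 1], 2)
        assert np.array_equal(w, [[1.0, -0.5], [-0.5, 1.0]])

    def test_four_prototypes(self):
        w = init_final_layer([0, 0, 1, 1], 2)
        expected = [[1, -0.5], [1, -0.5], [-0.5, 1], [-0.5, 1]]
        assert np.array_equal(w, expected)

    def test_single_class_all_ones(self):
        assert np.array_equal(init_final_layer([0, 0, 0], 1), np.ones((3, 1)))

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            init_final_layer([0, 2], 2)


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

class TestEmbed:
    def test_sigmoid_range(self, tiny_model, rng):
        z = embed(random_image(rng), tiny_model)
        assert z.min() >= 0.0 and z.max() <= 1.0
        assert z.shape[-1] == 6

    def test_deterministic(self, tiny_model, rng):
        im = random_image(rng)
        assert np.array_equal(embed(im, tiny_model), embed(im, tiny_model))

    def test_batched_equals_per_image(self, tiny_model, rng):
        ims = [random_image(rng, image_id=str(i)) for i in range(3)]
        batched = embed_batch(ims, tiny_model)
        stacked = np.stack([embed(im, tiny_model) for im in ims])
        np.testing.assert_allclose(batched, stacked, atol=1e-12)

    def test_shape_mismatch(self, tiny_model, rng):
        with pytest.raises(ValidationError):
            embed(LabeledImage(rng.uniform(0, 1, (32, 32, 1)), 0, "big"),
                  tiny_model)


class TestPrototypeDistances:
    def test_exact_match_zero(self, rng):
        z = rng.uniform(0, 1, (2, 3, 4))
        vecs = rng.uniform(0, 1, (5, 4))
        vecs[2] = z[1, 2]
        protos = PrototypeSet(vecs, np.zeros(5, dtype=int), 5)
        dist = prototype_distances(z, protos)
        assert dist[2, 1, 2] == pytest.approx(0.0, abs=1e-12)

    def test_zero_prototype_is_norm(self, rng):
        z = rng.uniform(0, 1, (2, 2, 3))
        protos = PrototypeSet(np.zeros((1, 3)), [0], 1)
        dist = prototype_distances(z, protos)
        np.testing.assert_allclose(dist[0], (z ** 2).sum(axis=-1), atol=1e-12)

    def test_triple_loop_oracle(self, rng):
        for _ in range(100):
            h, w, d = rng.integers(1, 9), rng.integers(1, 9), rng.integers(1, 17)
            m = rng.integers(1, 21)
            z = rng.uniform(0, 1, (h, w, d))
            vecs = rng.uniform(0, 1, (m, d))
            protos = PrototypeSet(vecs, np.zeros(m, dtype=int), m)
            dist = prototype_distances(z, protos)
            oracle = np.empty((m, h, w))
            for j in range(m):
                for r in range(h):
                    for c in range(w):
                        oracle[j, r, c] = ((z[r, c] - vecs[j]) ** 2).sum()
            np.testing.assert_allclose(dist, oracle, atol=1e-6)

    def test_dimension_mismatch(self, rng):
        protos = PrototypeSet(rng.uniform(0, 1, (2, 5)), [0, 1], 1)
        with pytest.raises(ValidationError):
            prototype_distances(rng.uniform(0, 1, (2, 2, 4)), protos)

    def test_nonnegative(self, rng):
        protos = PrototypeSet(rng.normal(0, 3, (4, 6)), np.zeros(4, int), 4)
        assert prototype_distances(rng.uniform(0, 1, (3, 3, 6)), protos).min() >= 0


class TestSimilarity:
    def test_zero_distance(self):
        assert similarity_from_distance(0.0, 1e-4) == pytest.approx(
            np.log(1e4), rel=1e-9)

    def test_limit_to_zero(self):
        assert similarity_from_distance(1e12) == pytest.approx(0.0, abs=1e-6)
        assert similarity_from_distance(1e12) > 0

    def test_strictly_decreasing(self, rng):
        pairs = np.sort(rng.uniform(0, 100, (1000, 2)), axis=1)
        pairs = pairs[pairs[:, 0] < pairs[:, 1]]
        s = similarity_from_distance(pairs)
        assert np.all(s[:, 0] > s[:, 1])

    def test_bounded(self, rng):
        s = similarity_from_distance(rng.uniform(0, 1e6, 1000), 1e-4)
        assert np.all(s > 0) and np.all(s <= np.log(1e4))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValidationError):
            similarity_from_distance(-0.1)

    def test_bad_eps(self):
        with pytest.raises(ValidationError):
            similarity_from_distance(1.0, eps=2.0)


class TestClassify:
    def test_probabilities_sum_to_one(self, tiny_model, rng):
        z = embed(random_image(rng), tiny_model)
        probs, top = classify(z, tiny_model.prototypes, tiny_model.final_weights)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert top.shape == (tiny_model.prototypes.m,)

    def test_zero_weights_uniform(self, tiny_model, rng):
        z = embed(random_image(rng), tiny_model)
        probs, _ = classify(z, tiny_model.prototypes,
                            np.zeros_like(tiny_model.final_weights))
        np.testing.assert_allclose(probs, 0.5, atol=1e-12)

    def test_end_to_end_oracle(self, rng):
        for _ in range(100):
            h, w, d, m = 3, 4, 5, 6
            z = rng.uniform(0, 1, (h, w, d))
            vecs = rng.uniform(0, 1, (m, d))
            class_of = rng.integers(0, 2, m)
            fw = rng.normal(0, 1, (m, 2))
            protos = PrototypeSet(vecs, class_of, m)
            probs, top = classify(z, protos, fw)
            # brute-force recomputation
            o_top = np.empty(m)
            for j in range(m):
                best = -np.inf
                for r in range(h):
                    for c in range(w):
                        dd = ((z[r, c] - vecs[j]) ** 2).sum()
                        best = max(best, np.log((dd + 1) / (dd + 1e-4)))
                o_top[j] = best
            logits = o_top @ fw
            o_probs = np.exp(logits - logits.max())
            o_probs /= o_probs.sum()
            np.testing.assert_allclose(top, o_top, atol=1e-8)
            np.testing.assert_allclose(probs, o_probs, atol=1e-8)
            assert probs.argmax() == o_probs.argmax()

    def test_permutation_equivariance(self, rng):
        h, w, d, m = 2, 2, 4, 6
        z = rng.uniform(0, 1, (h, w, d))
        vecs = rng.uniform(0, 1, (m, d))
        class_of = np.array([0, 0, 0, 1, 1, 1])
        fw = rng.normal(0, 1, (m, 2))
        perm = rng.permutation(m)
        p1, _ = classify(z, PrototypeSet(vecs, class_of, 3), fw)
        p2, _ = classify(z, PrototypeSet(vecs[perm], class_of[perm], 3), fw[perm])
        np.testing.assert_allclose(p1, p2, atol=1e-10)


# ---------------------------------------------------------------------------
# loss and training
# ---------------------------------------------------------------------------

def _loss_oracle(batch, params, cfg):
    """Loop-based recomputation of the training objective."""
    ce_sum, clst_sum, sep_sum = 0.0, 0.0, 0.0
    for im in batch:
        z = embed(im, params)
        dist = prototype_distances(z, params.prototypes)
        sim = np.log((dist + 1) / (dist + params.eps))
        top = sim.reshape(params.prototypes.m, -1).max(axis=1)
        logits = top @ params.final_weights
        p = np.exp(logits - logits.max())
        p /= p.sum()
        ce_sum += -np.log(p[im.label])
        same = params.prototypes.class_of == im.label
        per_proto_min = dist.reshape(params.prototypes.m, -1).min(axis=1)
        clst_sum += per_proto_min[same].min()
        sep_sum += per_proto_min[~same].min()
    n = len(batch)
    return (ce_sum / n + cfg.lambda_cluster * clst_sum / n
            - cfg.lambda_separation * sep_sum / n)


class TestLoss:
    def test_zero_coefficients_is_cross_entropy(self, tiny_model, rng):
        batch = [random_image(rng, label=i % 2, image_id=str(i)) for i in range(4)]
        cfg = TrainConfig(lambda_cluster=0.0, lambda_separation=0.0)
        got = loss(batch, tiny_model, cfg)
        ce = 0.0
        for im in batch:
            z = embed(im, tiny_model)
            probs, _ = classify(z, tiny_model.prototypes, tiny_model.final_weights)
            ce -= np.log(probs[im.label])
        assert got == pytest.approx(ce / len(batch), abs=1e-9)

    def test_cluster_cost_zero_on_exact_prototype(self, tiny_model, rng):
        im = random_image(rng, label=0)
        params = tiny_model.copy()
        z = embed(im, params)
        params.prototypes.vectors[0] = z[0, 0]  # class-0 prototype == a patch
        ce_only = loss([im], params, TrainConfig(lambda_cluster=0.0,
                                                 lambda_separation=0.0))
        with_cluster = loss([im], params, TrainConfig(lambda_cluster=5.0,
                                                      lambda_separation=0.0))
        assert with_cluster == pytest.approx(ce_only, abs=1e-9)

    def test_loop_oracle(self, tiny_model, rng):
        for _ in range(100):
            batch = [random_image(rng, label=int(rng.integers(0, 2)),
                                  image_id=str(i))
                     for i in range(int(rng.integers(1, 5)))]
            cfg = TrainConfig(lambda_cluster=float(rng.uniform(0, 1)),
                              lambda_separation=float(rng.uniform(0, 0.2)))
            assert loss(batch, tiny_model, cfg) == pytest.approx(
                _loss_oracle(batch, tiny_model, cfg), abs=1e-5)

    def test_bad_label(self, tiny_model, rng):
        with pytest.raises(ValidationError):
            loss([random_image(rng, label=3)], tiny_model, TrainConfig())

    def test_empty_batch(self, tiny_model):
        with pytest.raises(ValidationError):
            loss([], tiny_model, TrainConfig())


class TestTrainLocal:
    def test_frozen_backbone_unchanged(self, tiny_model, tiny_dataset, fast_cfg):
        cfg = fast_cfg.replace(frozen_backbone=True)
        out = train_local(tiny_dataset, tiny_model, cfg)
        for k in tiny_model.backbone_keys():
            assert np.array_equal(out.conv_weights[k], tiny_model.conv_weights[k])
        # add-on layers did move
        assert not np.array_equal(out.conv_weights['addon1_w'],
                                  tiny_model.conv_weights['addon1_w'])

    def test_input_params_not_mutated(self, tiny_model, tiny_dataset, fast_cfg):
        before = {k: v.copy() for k, v in tiny_model.conv_weights.items()}
        train_local(tiny_dataset, tiny_model, fast_cfg)
        for k, v in before.items():
            assert np.array_equal(tiny_model.conv_weights[k], v)

    def test_reproducible(self, tiny_model, tiny_dataset, fast_cfg):
        a = train_local(tiny_dataset, tiny_model, fast_cfg)
        b = train_local(tiny_dataset, tiny_model, fast_cfg)
        assert np.array_equal(a.prototypes.vectors, b.prototypes.vectors)
        for k in a.conv_weights:
            assert np.array_equal(a.conv_weights[k], b.conv_weights[k])

    def test_empty_dataset(self, tiny_model, fast_cfg):
        with pytest.raises(ValidationError):
            train_local([], tiny_model, fast_cfg)

    def test_separable_set_reaches_high_accuracy(self, tiny_world):
        from myth.cli import eval_model
        from myth.synthdata import WorldSpec, generate_dataset, train_test_split
        spec = WorldSpec(height=16, width=16, feature_contrast=0.5,
                         noise_sd=0.05, n_per_class=40, seed=11)
        data = generate_dataset(spec)
        train, test = train_test_split(data, 0.25, seed=0)
        model = build_model((16, 16, 1), depth=8, per_class=2, seed=1)
        cfg = TrainConfig(epochs=20, batch_size=16, seed=1)
        trained = train_local(train, model, cfg)
        res = eval_model(trained, train)
        assert res.balanced_accuracy >= 95.0


class TestGradients:
    def test_numeric_gradient_check(self, rng):
        """Hand-derived backprop matches central differences."""
        B, D, m = 2, 4, 4
        x = rng.uniform(0, 1, (B, 16, 16, 1))
        y = np.array([0, 1])
        conv = _net.init_small_cnn(rng, 1)
        conv.update(_net.init_addon(rng, 32, D))
        protos = rng.uniform(0, 1, (m, D))
        final = init_final_layer([0, 0, 1, 1], 2)
        class_of = np.array([0, 0, 1, 1])
        args = (1e-4, 0.8, 0.08)

        def f():
            z, _ = _net.encode(x, conv)
            value, _, _ = _net.head_forward(z, protos, final, class_of, y, *args)
            return value

        _, _, grads = _net.forward_backward(x, y, conv, protos, final,
                                            class_of, *args)
        h = 1e-6
        for key in list(conv) + ['prototypes', 'final_weights']:
            arr = {'prototypes': protos, 'final_weights': final}.get(key,
                                                                     conv.get(key))
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + h
                lp = f()
                arr[idx] = orig - h
                lm = f()
                arr[idx] = orig
                num = (lp - lm) / (2 * h)
                assert grads[key][idx] == pytest.approx(num, rel=1e-4, abs=1e-7)
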