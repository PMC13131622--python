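import numpy as np
import pytest

from bovw3d.bovw_encoding import ImageVector, PatchEncoding
from bovw3d.classify_interpret import (
    attention_scores,
    cross_val_auc,
    evaluate_auc,
    render_attention,
    train_classifier,
)
from bovw3d.rihog3d import Patch

from oracles import attention_bruteforce, auc_pair_counting


def make_vectors(X):
    out = []
    for i, row in enumerate(X):
        iv = ImageVector(f"img{i}", raw_usage=np.abs(row))
        n = np.linalg.norm(row)
        iv.normalized = row / n if n else row
        out.append(iv)
    return out


def separable_corpus(seed=0, n=30, informative=7, K=12):
    rng = np.random.default_rng(seed)
    X = np.abs(rng.normal(0.2, 0.05, size=(n, K)))
    y = np.array([i % 2 for i in range(n)])
    X[y == 1, informative] += 1.5
    return make_vectors(X), y


class TestTraining:
    def test_informative_word_gets_largest_weight(self):
        vectors, y = separable_corpus()
        model = train_classifier(vectors, y)
        assert np.argmax(np.abs(model.weights)) == 7
        # the word pushing toward class 1 carries positive weight for class 1
        assert model.weights[7] > 0

    def test_deterministic_fit(self):
        vectors, y = separable_corpus(seed=1)
        a = train_classifier(vectors, y).weights
        b = train_classifier(vectors, y).weights
        assert np.array_equal(a, b)

    def test_single_class_raises(self):
        vectors, _ = separable_corpus()
        with pytest.raises(ValueError, match="2 classes"):
            train_classifier(vectors, np.zeros(len(vectors)))

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(0)
        X = np.abs(rng.normal(size=(60, 10)))
        vectors = make_vectors(X)
        y = rng.permutation([0, 1] * 30)
        auc = cross_val_auc(vectors, y, n_folds=5, seed=0)
        assert 0.2 < auc < 0.8


class TestAuc:
    def test_perfect_separation(self):
        vectors, y = separable_corpus(seed=2)
        model = train_classifier(vectors, y)
        assert evaluate_auc(model, vectors, y) == 1.0

    def test_six_sample_toy_matches_pair_counting(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.4, 0.2])
        labels = np.array([1, 1, 1, 0, 0, 0])
        assert auc_pair_counting(scores, labels) == 1.0
        # swap one positive/negative pair of scores -> one discordant pair
        swapped = scores.copy()
        swapped[2], swapped[3] = swapped[3], swapped[2]
        assert auc_pair_counting(swapped, labels) == pytest.approx(8.0 / 9.0)
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(labels, swapped) == pytest.approx(8.0 / 9.0)

    def test_tied_scores_give_half(self):
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_multiclass_returns_confusion_matrix(self):
        rng = np.random.default_rng(4)
        X = np.abs(rng.normal(0.2, 0.05, size=(40, 8)))
        y = np.array([i % 4 for i in range(40)])
        for c in range(4):
            X[y == c, c] += 2.0
        vectors = make_vectors(X)
        model = train_classifier(vectors, y)
        cm = evaluate_auc(model, vectors, y)
        assert cm.shape == (4, 4)
        assert cm.sum() == 40
        assert np.trace(cm) == 40  # separable by construction


class TestAttention:
    def test_worked_example_ten_units_over_ten_patches(self):
        # one word contributing 10 units, spread equally over 10 equal-usage
        # patches: each patch receives exactly 1 unit and the sum is 10
        K = 3
        encs = [PatchEncoding(np.array([2.0, 0.0, 0.0])) for _ in range(10)]
        iv = ImageVector("img", raw_usage=np.array([20.0, 0.0, 0.0]))
        iv.normalized = np.array([1.0, 0.0, 0.0])
        from bovw3d.classify_interpret import ClassifierModel

        model = ClassifierModel(
            weights=np.array([10.0, 5.0, -3.0]), intercept=np.zeros(1),
            classes=np.array([0, 1]),
        )
        amap = attention_scores(model, iv, encs)
        assert np.allclose(amap.patch_scores, 1.0)
        assert amap.patch_scores.sum() == pytest.approx(10.0)

    def test_single_patch_receives_full_decision_value(self):
        rng = np.random.default_rng(1)
        coeffs = rng.normal(size=6)
        iv = ImageVector("img", raw_usage=np.abs(coeffs))
        tf = np.abs(coeffs) * 1.3
        iv.normalized = tf / np.linalg.norm(tf)
        from bovw3d.classify_interpret import ClassifierModel

        model = ClassifierModel(weights=rng.normal(size=6), intercept=np.zeros(1),
                                classes=np.array([0, 1]))
        amap = attention_scores(model, iv, [PatchEncoding(coeffs)])
        assert amap.patch_scores[0] == pytest.approx(float(model.weights @ iv.normalized))

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(7)
        coeffs = rng.normal(size=(5, 4))
        coeffs[:, 3] = 0.0  # a word with zero usage contributes nothing
        encs = [PatchEncoding(c) for c in coeffs]
        usage = np.abs(coeffs).sum(axis=0)
        iv = ImageVector("img", raw_usage=usage)
        tf = usage * np.array([1.0, 2.0, 0.5, 1.5])
        iv.normalized = tf / np.linalg.norm(tf)
        from bovw3d.classify_interpret import ClassifierModel

        w = rng.normal(size=4)
        model = ClassifierModel(weights=w, intercept=np.zeros(1), classes=np.array([0, 1]))
        amap = attention_scores(model, iv, encs)
        expect = attention_bruteforce(w, iv.normalized, np.abs(coeffs))
        assert np.allclose(amap.patch_scores, expect, atol=1e-12)

    def test_conservation_over_random_instances(self):
        rng = np.random.default_rng(12)
        from bovw3d.classify_interpret import ClassifierModel

        for _ in range(50):
            P, K = rng.integers(1, 20), rng.integers(2, 30)
            coeffs = rng.normal(size=(P, K))
            usage = np.abs(coeffs).sum(axis=0)
            iv = ImageVector("img", raw_usage=usage)
            tf = usage * (1.0 + rng.random(K))
            iv.normalized = tf / np.linalg.norm(tf)
            w = rng.normal(size=K)
            model = ClassifierModel(weights=w, intercept=np.zeros(1), classes=np.array([0, 1]))
            amap = attention_scores(model, iv, [PatchEncoding(c) for c in coeffs])
            linear = float(w @ iv.normalized)
            assert amap.patch_scores.sum() == pytest.approx(linear, rel=1e-6)

    def test_class_swap_negates_scores(self):
        vectors, y = separable_corpus(seed=5)
        m1 = train_classifier(vectors, y, C=1.0)
        m2 = train_classifier(vectors, 1 - y, C=1.0)
        rng = np.random.default_rng(0)
        coeffs = rng.normal(size=(6, 12))
        usage = np.abs(coeffs).sum(axis=0)
        iv = ImageVector("img", raw_usage=usage)
        iv.normalized = usage / np.linalg.norm(usage)
        encs = [PatchEncoding(c) for c in coeffs]
        s1 = attention_scores(m1, iv, encs).patch_scores
        s2 = attention_scores(m2, iv, encs).patch_scores
        assert np.allclose(s1, -s2, atol=1e-4)

    def test_provenance_mismatch_rejected(self):
        iv = ImageVector("img", raw_usage=np.array([5.0, 5.0]))
        iv.normalized = np.array([1.0, 0.0])
        from bovw3d.classify_interpret import ClassifierModel

        model = ClassifierModel(weights=np.ones(2), intercept=np.zeros(1),
                                classes=np.array([0, 1]))
        with pytest.raises(ValueError, match="provenance"):
            attention_scores(model, iv, [PatchEncoding(np.array([1.0, 0.0]))])


def patch_at(z, y, x, edge):
    half = edge // 2
    return Patch(
        center=(z, y, x), edge_len=edge, intensities=None, in_mask_fraction=1.0,
        slices=(slice(z - half, z + half + 1), slice(y - half, y + half + 1),
                slice(x - half, x + half + 1)),
    )


class TestRendering:
    def test_uniform_spread_conserves_score(self):
        p = patch_at(5, 5, 5, 5)
        amap = render_attention((11, 11, 11), [p], np.array([2.5]))
        inside = amap.volume_render[p.slices]
        assert np.allclose(inside, 2.5 / 125)
        assert amap.volume_render.sum() == pytest.approx(2.5)
        outside = amap.volume_render.copy()
        outside[p.slices] = 0
        assert not outside.any()

    def test_overlapping_patches_accumulate(self):
        # voxelwise oracle on a 10^3 toy
        p1, p2 = patch_at(4, 4, 4, 5), patch_at(6, 6, 6, 5)
        s = np.array([1.0, 2.0])
        amap = render_attention((10, 10, 10), [p1, p2], s)
        expect = np.zeros((10, 10, 10))
        expect[p1.slices] += 1.0 / 125
        expect[p2.slices] += 2.0 / 125
        assert np.allclose(amap.volume_render, expect)

    def test_constant_map_rescales_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            amap = render_attention((5, 5, 5), [], np.zeros(0))
        assert not amap.rescaled.any()

    def test_rescaled_in_unit_interval(self):
        p1, p2 = patch_at(2, 2, 2, 3), patch_at(7, 7, 7, 3)
        amap = render_attention((10, 10, 10), [p1, p2], np.array([-1.0, 3.0]))
        assert amap.rescaled.min() == 0.0 and amap.rescaled.max() == 1.0

    def test_positive_only_mode_drops_negative_patches(self):
        p1, p2 = patch_at(2, 2, 2, 3), patch_at(7, 7, 7, 3)
        amap = render_attention((10, 10, 10), [p1, p2], np.array([-1.0, 3.0]),
                                positive_only=True)
        assert amap.volume_render.min() == 0.0
        assert amap.volume_render.sum() == pytest.approx(3.0)

    def test_out_of_bounds_patch_rejected(self):
        p = patch_at(1, 1, 1, 5)  # slices start at -1
        with pytest.raises(ValueError, match="bounds"):
            render_attention((10, 10, 10), [p], np.array([1.0]))

    def test_gaussian_mode_conserves_total(self):
        p = patch_at(5, 5, 5, 5)
        amap = render_attention((11, 11, 11), [p], np.array([2.0]), mode="gaussian")
        assert amap.volume_render.sum() == pytest.approx(2.0)
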