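"""Evaluation metrics against brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tomocycle.metrics import (
    GaussianMoments, coverage, density, evaluate_suite, fid, inception_score,
    knn_radii, moments, precision, recall, ssim3d, classification_accuracy,
    REPORT_KEYS,
)
from tomocycle.volume import DomainDataset, Volume


from oracles import brute_prdc, brute_radii


class TestKnnRadii:
    def test_two_points_1d(self):
        idx = knn_radii([[0.0], [1.0]], k=1)
        np.testing.assert_allclose(idx.radii, [1.0, 1.0])

    def test_matches_brute_force(self, rng):
        X = rng.normal(size=(50, 4))
        for k in (1, 3, 5):
            np.testing.assert_allclose(knn_radii(X, k).radii, brute_radii(X, k))

    def test_k_at_least_n_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="k"):
            knn_radii(X, 5)

    def test_duplicates_flagged(self):
        with pytest.warns(UserWarning, match="duplicate"):
            idx = knn_radii([[0.0], [0.0], [0.0]], k=1)
        assert np.all(idx.radii == 0.0)


class TestManifoldMetrics:
    def test_hand_instance(self):
        X, Y = [[0.0], [1.0]], [[0.5], [3.0]]
        assert precision(X, Y, 1) == 0.5
        assert recall(X, Y, 1) == 1.0
        assert density(X, Y, 1) == 1.0
        assert coverage(X, Y, 1) == 1.0

    def test_identical_sets(self, rng):
        X = rng.normal(size=(10, 3))
        assert precision(X, X, 2) == 1.0
        assert recall(X, X, 2) == 1.0
        assert coverage(X, X, 2) == 1.0

    def test_distant_fakes_score_zero(self, rng):
        X = rng.normal(size=(10, 3))
        Y = X + 1e6
        assert precision(X, Y, 1) == 0.0
        assert density(X, Y, 1) == 0.0
        assert coverage(X, Y, 1) == 0.0

    def test_oracle_equivalence_sweep(self):
        """Exact agreement with the double-loop oracle on random instances."""
        rng = np.random.default_rng(123)
        for trial in range(60):
            n, m = rng.integers(8, 61, size=2)
            d = rng.integers(1, 9)
            k = int(rng.choice([1, 3, 5]))
            X = rng.normal(size=(n, d))
            Y = rng.normal(size=(m, d)) + rng.normal() * 0.5
            bp, br, bd, bc = brute_prdc(X, Y, k)
            assert precision(X, Y, k) == bp
            assert recall(X, Y, k) == br
            assert density(X, Y, k) == pytest.approx(bd, abs=1e-12)
            assert coverage(X, Y, k) == bc

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            precision(np.zeros((0, 2)), np.zeros((3, 2)), 1)


class TestInceptionScore:
    def test_identical_rows_score_one(self):
        assert inception_score(np.full((12, 4), 0.25)) == pytest.approx(1.0)

    def test_balanced_one_hot_scores_c(self):
        probs = np.eye(4)[np.arange(20) % 4]
        assert inception_score(probs) == pytest.approx(4.0)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6), st.integers(1, 40))
    def test_bounded_by_class_count(self, seed, c, n):
        p = np.random.default_rng(seed).dirichlet(np.ones(c) * 0.3, size=n)
        score = inception_score(p)
        assert 1.0 - 1e-9 <= score <= c + 1e-9

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            inception_score(np.array([[0.5, 0.2]]))


class TestFID:
    def test_identical_moments_zero(self, rng):
        m = moments(rng.normal(size=(40, 5)))
        assert fid(m, m) == pytest.approx(0.0, abs=1e-10)

    def test_1d_closed_form(self):
        a = GaussianMoments([0.0], [[1.0]])
        b = GaussianMoments([1.0], [[1.0]])
        assert fid(a, b) == pytest.approx(1.0, abs=1e-10)

    def test_diagonal_closed_form(self, rng):
        mu_r, mu_g = rng.normal(size=3), rng.normal(size=3)
        sr, sg = rng.uniform(0.5, 2.0, 3), rng.uniform(0.5, 2.0, 3)
        a = GaussianMoments(mu_r, np.diag(sr**2))
        b = GaussianMoments(mu_g, np.diag(sg**2))
        expected = ((mu_r - mu_g) ** 2).sum() + ((sr - sg) ** 2).sum()
        assert fid(a, b) == pytest.approx(expected, abs=1e-8)

    def test_symmetric(self, rng):
        a = moments(rng.normal(size=(30, 4)))
        b = moments(rng.normal(size=(30, 4)) * 2 + 1)
        assert fid(a, b) == pytest.approx(fid(b, a), abs=1e-8)

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dims"):
            fid(GaussianMoments([0.0], [[1.0]]), GaussianMoments([0, 0], np.eye(2)))


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        a = rng.normal(size=(16,) * 3)
        assert ssim3d(a, a) == pytest.approx(1.0)

    def test_sign_flip_negative(self, rng):
        a = rng.normal(size=(16,) * 3)
        a -= a.mean()
        assert ssim3d(a, -a) < 0.0

    def test_constant_shift_lowers_but_stays_positive(self):
        from tomocycle.simulate import ToyStructureSpec, make_toy_density

        a = make_toy_density(ToyStructureSpec("dumbbell", 16, seed=1)).data.astype(float)
        val = ssim3d(a, a + 0.1, data_range=1.0)
        assert 0.0 < val < 1.0

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            ssim3d(np.zeros((8,) * 3), np.zeros((9,) * 3))


class _FixedClassifier:
    def __init__(self, outputs):
        self.outputs = outputs

    def predict(self, volumes):
        return self.outputs[: len(volumes)]


def _labelled_dataset(rng, labels):
    vols = [Volume(rng.normal(size=(8,) * 3).astype(np.float32)) for _ in labels]
    return DomainDataset(vols, "S", labels=list(labels))


class TestClassificationAccuracy:
    def test_hand_counted_fraction(self, rng):
        ds = _labelled_dataset(rng, ["a", "a", "b", "b"])
        clf = _FixedClassifier(["a", "b", "b", "b"])  # 3 of 4 correct
        assert classification_accuracy(clf, ds) == pytest.approx(0.75)

    def test_random_classifier_near_chance(self, rng):
        labels = ["a", "b", "c", "d"] * 50
        ds = _labelled_dataset(rng, labels)
        guesser = _FixedClassifier(list(rng.choice(["a", "b", "c", "d"], size=200)))
        acc = classification_accuracy(guesser, ds)
        # binomial(200, 1/4): 5 sigma is about 0.153
        assert abs(acc - 0.25) < 0.155

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classification_accuracy(_FixedClassifier([]), DomainDataset([], "S", labels=[]))


class _IdentityEmbedder:
    """Features = flattened volumes; posteriors concentrate on class 'a'."""

    classes = ["a", "b"]

    def features(self, volumes):
        return np.stack([v.data.ravel() for v in volumes]).astype(np.float64)

    def predict_proba(self, volumes):
        return np.tile([0.9, 0.1], (len(volumes), 1))

    def predict(self, volumes):
        return ["a"] * len(volumes)


class TestEvaluateSuite:
    def test_generated_equals_real_identities(self, rng):
        labels = ["a", "a", "b", "b", "a", "b"]
        ds = _labelled_dataset(rng, labels)
        report = evaluate_suite(ds, ds, _IdentityEmbedder(), k=2)
        assert tuple(report) == REPORT_KEYS
        assert report["precision"] == 1.0
        assert report["recall"] == 1.0
        assert report["coverage"] == 1.0
        assert report["fid"] == pytest.approx(0.0, abs=1e-8)
        assert report["ssim"] == pytest.approx(1.0)

    def test_per_sample_report_columns(self, rng):
        from tomocycle.metrics import per_sample_report

        labels = ["a", "b"] * 4
        ds = _labelled_dataset(rng, labels)
        frame = per_sample_report(ds, ds, _IdentityEmbedder(), k=2)
        assert len(frame) == len(ds)
        assert frame["in_real_manifold"].all()
        np.testing.assert_allclose(frame["ssim_nearest"], 1.0)

    def test_pure_noise_scores_near_zero(self, rng):
        labels = ["a", "b"] * 5
        real = _labelled_dataset(rng, labels)
        far = DomainDataset(
            [Volume(v.data + 100.0) for v in real.volumes], "S", labels=labels
        )
        report = evaluate_suite(real, far, _IdentityEmbedder(), k=2)
        assert report["precision"] == 0.0
        assert report["coverage"] == 0.0
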