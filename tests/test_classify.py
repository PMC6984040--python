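"""Monte-Carlo CV, discriminants, SVMs, sparse selection, VAE and CNN."""

import warnings

import numpy as np
import pytest

from rsfi.classify import (
    ConnectomeCNN,
    McCvConfig,
    SparseLinearSVM,
    VaeAugmenter,
    choose_lambda,
    cnn_fit_eval,
    evaluate,
    make_classifier,
    mc_splits,
    pair_index,
    pca_fit_transform,
    run_mc_cv,
    sparse_svm_select,
)
from rsfi.features import matricize, vectorize_upper


def cohort(n=79, n_pat=50):
    return {f"s{i:02d}": ("patient" if i < n_pat else "control")
            for i in range(n)}


class TestSplits:
    def test_seventy_thirty_counts(self):
        labels = cohort()
        splits = mc_splits(labels, McCvConfig(n_reps=3, seed=0))
        for train, test in splits:
            assert len(train) == 55 and len(test) == 24
            assert not set(train) & set(test)

    def test_deterministic_given_seed(self):
        labels = cohort(20, 10)
        a = mc_splits(labels, McCvConfig(n_reps=5, seed=7))
        b = mc_splits(labels, McCvConfig(n_reps=5, seed=7))
        assert a == b

    def test_stratification_preserves_ratio(self):
        labels = cohort()
        for train, _ in mc_splits(labels, McCvConfig(n_reps=10, seed=1)):
            n_pat = sum(labels[s] == "patient" for s in train)
            expected = 0.7 * 50
            assert abs(n_pat - expected) <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            mc_splits({"a": "x", "b": "x"}, McCvConfig())


class TestEvaluate:
    def test_perfect_predictions(self):
        truth = ["patient"] * 3 + ["control"] * 2
        out = evaluate(truth, truth)
        assert out["sensitivity"] == 1.0 and out["specificity"] == 1.0

    def test_all_positive_predictions(self):
        truth = ["patient", "control", "control"]
        out = evaluate(["patient"] * 3, truth)
        assert out["sensitivity"] == 1.0 and out["specificity"] == 0.0

    def test_counts_from_confusion(self):
        # 40/50 positives correct, 45/50 negatives correct
        truth = ["patient"] * 50 + ["control"] * 50
        preds = (["patient"] * 40 + ["control"] * 10
                 + ["patient"] * 5 + ["control"] * 45)
        out = evaluate(preds, truth)
        assert out["sensitivity"] == pytest.approx(0.8)
        assert out["specificity"] == pytest.approx(0.9)

    def test_missing_class_reported_as_nan(self):
        out = evaluate(["control", "control"], ["control", "control"])
        assert np.isnan(out["sensitivity"])


class TestPca:
    def test_exact_subspace_reconstruction(self, rng):
        basis = rng.standard_normal((3, 30))
        coords = rng.standard_normal((50, 3))
        X = coords @ basis
        tr, te, pca = pca_fit_transform(X, X[:5], n_components=3)
        recon = pca.inverse_transform(tr)
        np.testing.assert_allclose(recon, X, atol=1e-9)
        assert np.all(np.diff(pca.explained_variance_) <= 1e-9)

    def test_too_many_components_rejected(self, rng):
        X = rng.standard_normal((10, 5))
        with pytest.raises(ValueError, match="n_components"):
            pca_fit_transform(X, X, n_components=8)


class TestDiscriminants:
    def test_separated_gaussians_classified(self, rng):
        X = np.vstack([rng.standard_normal((100, 12)),
                       rng.standard_normal((100, 12)) + 3.0])
        y = ["patient"] * 100 + ["control"] * 100
        for kind in ("lda", "qda"):
            pipe = make_classifier(kind)
            pipe.named_steps["pca"].n_components = 5
            pipe.fit(X[::2], np.asarray(y)[::2])
            acc = np.mean(pipe.predict(X[1::2]) == np.asarray(y)[1::2])
            assert acc > 0.95

    def test_identical_distributions_near_chance(self, rng):
        X = rng.standard_normal((400, 10))
        y = np.array(["patient", "control"] * 200)
        pipe = make_classifier("lda")
        pipe.named_steps["pca"].n_components = 5
        pipe.fit(X[:300], y[:300])
        acc = np.mean(pipe.predict(X[300:]) == y[300:])
        assert abs(acc - 0.5) < 1.96 * np.sqrt(0.25 / 100)

    def test_qda_beats_lda_on_covariance_difference(self, rng):
        wins = 0
        for rep in range(30):
            r = np.random.default_rng(rep)
            A = r.standard_normal((60, 6)) * 0.5
            B = r.standard_normal((60, 6)) * 2.0
            X = np.vstack([A, B])
            y = np.array(["patient"] * 60 + ["control"] * 60)
            idx = r.permutation(120)
            tr, te = idx[:80], idx[80:]
            accs = {}
            for kind in ("lda", "qda"):
                pipe = make_classifier(kind)
                pipe.named_steps["pca"].n_components = 4
                pipe.fit(X[tr], y[tr])
                accs[kind] = np.mean(pipe.predict(X[te]) == y[te])
            wins += accs["qda"] >= accs["lda"]
        assert wins > 15  # QDA matches the generating model on average


class TestSvm:
    def test_separable_blobs_linear_kernel(self, rng):
        X = np.vstack([rng.standard_normal((40, 2)),
                       rng.standard_normal((40, 2)) + 8.0])
        y = np.array(["a"] * 40 + ["b"] * 40)
        pipe = make_classifier("svm-linear")
        pipe.named_steps["pca"].n_components = 2
        pipe.fit(X, y)
        assert np.mean(pipe.predict(X) == y) == 1.0

    @staticmethod
    def _xor(seed, n_per=100):
        r = np.random.default_rng(seed)
        centers = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]])
        X = (r.standard_normal((4 * n_per, 2)) * 0.3
             + np.repeat(centers, n_per, axis=0))
        y = np.array(["a"] * 2 * n_per + ["b"] * 2 * n_per)
        return X, y

    def test_xor_needs_nonlinear_kernel(self):
        X_tr, y_tr = self._xor(0)
        X_te, y_te = self._xor(1, n_per=250)  # balanced symmetric test set
        accs = {}
        for kind in ("svm-linear", "svm-rbf"):
            pipe = make_classifier(kind)
            pipe.named_steps["pca"].n_components = 2
            pipe.fit(X_tr, y_tr)
            accs[kind] = np.mean(pipe.predict(X_te) == y_te)
        # a line can capture at most 3 of the 4 XOR blobs (75% ceiling);
        # the rbf kernel separates the layout almost perfectly
        assert accs["svm-linear"] < 0.8
        assert accs["svm-rbf"] > 0.9
        assert accs["svm-rbf"] > accs["svm-linear"] + 0.15

    def test_vanishing_c_degenerates_to_majority(self, rng):
        X = np.vstack([rng.standard_normal((30, 2)),
                       rng.standard_normal((60, 2)) + 4.0])
        y = np.array(["min"] * 30 + ["maj"] * 60)
        pipe = make_classifier("svm-rbf", C=1e-4)
        pipe.named_steps["pca"].n_components = 2
        pipe.fit(X, y)
        preds = pipe.predict(X)
        assert np.mean(preds == "maj") > 0.95


class TestSparseSvm:
    def test_single_informative_coordinate_selected(self, rng):
        X = rng.standard_normal((60, 20)) * 0.2
        y = np.array(["a"] * 30 + ["b"] * 30)
        X[:30, 7] += 2.0
        X[30:, 7] -= 2.0
        est = SparseLinearSVM(lam=0.1).fit(X, y)
        assert est.support_.tolist() == [7]

    def test_large_lambda_empties_support(self, rng):
        X = rng.standard_normal((40, 10))
        y = np.array(["a", "b"] * 20)
        est = SparseLinearSVM(lam=100.0).fit(X, y)
        assert est.support_.size == 0

    def test_regularization_path_shrinks_with_lambda(self):
        # ||w||_1 is non-increasing in lambda (guaranteed by the objective);
        # support cardinality follows suit away from the degenerate
        # near-zero-lambda regime where LP optima are not unique
        X = np.random.default_rng(0).standard_normal((50, 30))
        y = np.array(["a"] * 25 + ["b"] * 25)
        fits = [SparseLinearSVM(lam=lam).fit(X, y)
                for lam in (0.001, 0.01, 0.1, 1.0)]
        norms = [np.abs(f.coef_).sum() for f in fits]
        assert norms == sorted(norms, reverse=True)
        sizes = [f.support_.size for f in fits[1:]]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_lambda_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            SparseLinearSVM(lam=0.0).fit(rng.standard_normal((4, 3)),
                                         np.array(["a", "b", "a", "b"]))

    def test_salience_graph_maps_support_to_roi_pairs(self, rng):
        n = 8
        d = n * (n - 1) // 2
        X = rng.standard_normal((40, d)) * 0.2
        idx = pair_index(n).index((2, 5))
        X[:20, idx] += 2.0
        X[20:, idx] -= 2.0
        y = np.array(["patient"] * 20 + ["control"] * 20)
        names = [f"R{i}" for i in range(n)]
        model, graph = sparse_svm_select(X, y, lam=0.1, roi_names=names)
        assert ("R2", "R5") in {(a, b) for a, b, _ in graph.edges}
        assert len(graph.edges) == model.support.size
        g = graph.to_networkx()
        assert g.number_of_edges() == len(graph.edges)

    def test_choose_lambda_returns_grid_member(self, rng):
        X = rng.standard_normal((40, 10))
        X[:20, 3] += 3.0
        y = np.array(["a"] * 20 + ["b"] * 20)
        lam = choose_lambda(X, y, grid=(0.3, 0.03), n_folds=4)
        assert lam in (0.3, 0.03)


class TestVae:
    def test_degenerate_distribution_reproduced(self, rng):
        v = rng.standard_normal(28)
        X = np.tile(v, (25, 1))
        aug = VaeAugmenter(kind="lead", hidden=(32, 8), epochs=20, seed=0).fit(X)
        samples = aug.sample(10)
        assert np.abs(samples - v[None, :]).max() < 1e-8

    def test_sample_moments_match_class(self, rng):
        X = rng.standard_normal((60, 45)) * 2.0 + 1.0
        aug = VaeAugmenter(kind="dtw", hidden=(32, 8), epochs=30, seed=1).fit(X)
        S = aug.sample(500)
        pooled_sd = X.std(axis=0)
        assert np.max(np.abs(S.mean(axis=0) - X.mean(axis=0)) / pooled_sd) < 0.1

    def test_matricized_samples_respect_symmetry(self, rng):
        X = rng.standard_normal((25, 10 * 9 // 2))
        aug = VaeAugmenter(kind="lead", hidden=(16, 4), epochs=10, seed=2).fit(X)
        M = aug.sample_matrices(3)
        for m in M:
            np.testing.assert_allclose(m, -m.T, atol=1e-12)

    def test_too_few_vectors_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 20"):
            VaeAugmenter().fit(rng.standard_normal((5, 10)))


class TestCnn:
    @staticmethod
    def mats(rng, n_per=30, shift=0.0):
        A = rng.standard_normal((n_per, 12, 12))
        B = rng.standard_normal((n_per, 12, 12))
        B[:, 2, 7] += shift
        B[:, 7, 2] += shift
        return np.vstack([A, B]), np.array(["control"] * n_per
                                           + ["patient"] * n_per)

    def test_learns_separable_pattern(self, rng):
        X, y = self.mats(rng, shift=5.0)
        clf = ConnectomeCNN(filters1=8, filters2=16, dense=16, epochs=60,
                            seed=0).fit(X, y)
        X2, y2 = self.mats(np.random.default_rng(99), shift=5.0)
        assert np.mean(clf.predict(X2) == y2) > 0.9

    def test_augmentation_never_touches_test_fold(self, rng):
        n_sub = 24
        labels = {f"s{i:02d}": ("patient" if i < 12 else "control")
                  for i in range(n_sub)}
        mats = np.stack([matricize(rng.standard_normal(8 * 7 // 2), "lead")
                         for _ in range(2 * n_sub)])
        subs = [f"s{i:02d}" for i in range(n_sub)] * 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = cnn_fit_eval(
                mats, subs, labels, kind="lead",
                config=McCvConfig(n_reps=2, seed=0), augmented=True,
                cnn_params={"filters1": 4, "filters2": 8, "dense": 8,
                            "epochs": 5},
                vae_params={"hidden": (16, 4), "epochs": 5, "min_train": 5},
            )
        assert len(rep.rows) == 2
        assert rep.classifier == "cnn+vae"

    def test_effect_monotonicity_small_probe(self):
        # accuracy grows with the planted difference
        accs = []
        for shift in (0.0, 5.0):
            X, y = self.mats(np.random.default_rng(5), shift=shift)
            X2, y2 = self.mats(np.random.default_rng(6), shift=shift)
            clf = ConnectomeCNN(filters1=8, filters2=16, dense=16,
                                epochs=60, seed=1).fit(X, y)
            accs.append(np.mean(clf.predict(X2) == y2))
        assert accs[1] > accs[0] + 0.2


def test_run_mc_cv_keeps_subject_records_together(rng):
    labels = {f"s{i}": ("patient" if i % 2 else "control") for i in range(12)}
    subs = [f"s{i}" for i in range(12)] * 2
    X = rng.standard_normal((24, 30))
    rep = run_mc_cv(X, subs, labels, "lda", McCvConfig(n_reps=3, seed=0))
    assert len(rep.rows) == 3
    summary = rep.summary()
    assert 0.0 <= summary["accuracy_mean"] <= 1.0
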