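"""From-scratch classifiers: oracles, symmetries, and solver correctness."""

import numpy as np
import pytest
from scipy.special import expit

from radcog.classifiers import (
    GaussianNaiveBayes,
    NeuralNetClassifier,
    RBFSupportVectorMachine,
    Standardized,
    class_weights,
    make_classifier,
    rbf_kernel,
)


class TestClassWeights:
    def test_balanced_labels_unit_weights(self):
        w = class_weights([0, 1] * 10)
        assert w == {0: 1.0, 1: 1.0}

    def test_95_5_imbalance(self):
        w = class_weights([0] * 95 + [1] * 5)
        assert w[1] == pytest.approx(10.0)
        assert w[0] == pytest.approx(100 / 190)

    def test_weight_times_count_balances(self, rng):
        y = (rng.random(200) < 0.2).astype(int)
        w = class_weights(y)
        assert w[0] * (y == 0).sum() == pytest.approx(w[1] * (y == 1).sum())
        assert w[0] <= 1.0 <= w[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights([1, 1, 1])


class TestGaussianNaiveBayes:
    def test_uniform_priors_regardless_of_imbalance(self, rng):
        X = rng.normal(size=(100, 3))
        y = np.r_[np.zeros(90, int), np.ones(10, int)]
        m = GaussianNaiveBayes().fit(X, y)
        assert m.class_prior_.tolist() == [0.5, 0.5]

    def test_symmetric_means_give_half_posterior(self):
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        X += np.array([[0.1], [-0.1], [0.1], [-0.1]])  # equal variances
        y = np.array([0, 0, 1, 1])
        m = GaussianNaiveBayes().fit(X, y)
        assert m.predict_proba([[0.0]])[0] == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_posterior_matches_closed_form_bayes_product(self):
        X = np.array([[1.0, 2.0], [3.0, 1.0], [6.0, 7.0], [8.0, 9.0]])
        y = np.array([0, 0, 1, 1])
        m = GaussianNaiveBayes().fit(X, y)
        q = np.array([4.0, 5.0])

        def normal_pdf(x, mu, var):
            return np.exp(-((x - mu) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)

        # independent arithmetic: moments and product rule written out
        like = []
        for cls in (0, 1):
            rows = X[y == cls]
            p = 0.5
            for j in range(2):
                mu = rows[:, j].mean()
                var = ((rows[:, j] - mu) ** 2).mean()
                p *= normal_pdf(q[j], mu, var)
            like.append(p)
        expected = like[1] / (like[0] + like[1])
        assert m.predict_score([q])[0] == pytest.approx(expected, abs=1e-12)

    def test_posteriors_normalize(self, rng):
        X = rng.normal(size=(40, 4))
        y = (rng.random(40) < 0.3).astype(int)
        m = GaussianNaiveBayes().fit(X, y)
        P = m.predict_proba(rng.normal(size=(25, 4)))
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_monotone_in_discriminative_feature(self):
        # only the class means differ, in feature 0; posterior for class 1
        # must increase along it
        rng = np.random.default_rng(0)
        X0 = rng.normal([0, 0], 1.0, size=(200, 2))
        X1 = rng.normal([2, 0], 1.0, size=(200, 2))
        m = GaussianNaiveBayes().fit(
            np.vstack([X0, X1]), np.r_[np.zeros(200, int), np.ones(200, int)]
        )
        grid = np.column_stack([np.linspace(-3, 5, 50), np.zeros(50)])
        s = m.predict_score(grid)
        assert (np.diff(s) > 0).all()

    def test_far_query_stays_finite_and_normalized(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        m = GaussianNaiveBayes().fit(X, y)
        P = m.predict_proba([[1e6, -1e6]])
        assert np.isfinite(P).all() and P.sum() == pytest.approx(1.0)

    def test_label_swap_inverts_score(self, rng):
        X = rng.normal(size=(30, 3))
        y = (rng.random(30) < 0.4).astype(int)
        q = rng.normal(size=(10, 3))
        a = GaussianNaiveBayes().fit(X, y).predict_score(q)
        b = GaussianNaiveBayes().fit(X, 1 - y).predict_score(q)
        assert np.allclose(a, 1 - b, atol=1e-12)

    def test_matches_sklearn_reference(self, rng):
        sklearn_nb = pytest.importorskip("sklearn.naive_bayes")
        X = rng.normal(size=(60, 4))
        y = (rng.random(60) < 0.3).astype(int)
        ours = GaussianNaiveBayes().fit(X, y)
        ref = sklearn_nb.GaussianNB(priors=[0.5, 0.5]).fit(X, y)
        q = rng.normal(size=(15, 4))
        assert np.allclose(ours.predict_score(q), ref.predict_proba(q)[:, 1], atol=1e-9)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            GaussianNaiveBayes().fit(rng.normal(size=(5, 2)), np.ones(5, int))

    def test_json_round_trip(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        m = GaussianNaiveBayes().fit(X, y)
        m2 = GaussianNaiveBayes.from_dict(m.to_dict())
        q = rng.normal(size=(5, 2))
        assert np.allclose(m.predict_score(q), m2.predict_score(q))


class TestRBFSupportVectorMachine:
    def test_separable_toy_perfect_training_accuracy(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 3.0], [3.0, 4.0]])
        y = np.array([0, 0, 1, 1])
        m = RBFSupportVectorMachine(C=1.0, gamma=0.5).fit(X, y)
        pred = (m.decision_function(X) > 0).astype(int)
        assert (pred == y).all()

    def test_matches_reference_solver_on_toy(self):
        svm_mod = pytest.importorskip("sklearn.svm")
        X = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 3.0], [3.0, 4.0]])
        y = np.array([0, 0, 1, 1])
        ours = RBFSupportVectorMachine(C=1.0, gamma=0.5, tol=1e-5).fit(X, y)
        ref = svm_mod.SVC(C=1.0, gamma=0.5, tol=1e-5).fit(X, y)
        assert np.allclose(
            ours.decision_function(X), ref.decision_function(X), atol=1e-3
        )

    def test_matches_reference_solver_weighted_realistic(self, rng):
        svm_mod = pytest.importorskip("sklearn.svm")
        X = rng.normal(size=(120, 4))
        y = (X @ rng.normal(size=4) + rng.normal(size=120) > 0.8).astype(int)
        w = class_weights(y)
        Xs = (X - X.mean(0)) / X.std(0)
        ours = RBFSupportVectorMachine(tol=1e-4).fit(Xs, y, class_weight=w)
        ref = svm_mod.SVC(C=1.0, gamma="scale", class_weight=w, tol=1e-4).fit(Xs, y)
        d_ours, d_ref = ours.decision_function(Xs), ref.decision_function(Xs)
        assert np.corrcoef(d_ours, d_ref)[0, 1] > 0.9999
        assert np.abs(d_ours - d_ref).max() < 0.01

    def test_mirror_symmetric_data_zero_at_center(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        m = RBFSupportVectorMachine(C=1.0, gamma=0.3, tol=1e-6).fit(X, y)
        assert abs(m.decision_function([[0.0]])[0]) < 1e-3
        assert m.predict_score([[0.0]])[0] == pytest.approx(0.5, abs=1e-3)

    def test_free_support_vectors_sit_on_unit_margin(self, rng):
        X = np.vstack([rng.normal(-1.5, 1.0, (30, 2)), rng.normal(1.5, 1.0, (30, 2))])
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        m = RBFSupportVectorMachine(C=1.0, gamma=0.5, tol=1e-6).fit(X, y)
        d = m.decision_function(m.support_vectors_)
        free = np.abs(m.dual_coef_) < 1.0 - 1e-6
        assert free.any()
        assert np.allclose(np.abs(d[free]), 1.0, atol=1e-3)

    def test_far_field_decision_approaches_bias(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        m = RBFSupportVectorMachine().fit(X, y)
        far = np.array([[500.0, -500.0]])
        assert m.decision_function(far)[0] == pytest.approx(m.intercept_, abs=1e-9)

    def test_duplicated_data_with_halved_C_same_decision(self, rng):
        X = np.vstack([rng.normal(-1, 1, (15, 2)), rng.normal(1, 1, (15, 2))])
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        a = RBFSupportVectorMachine(C=1.0, gamma=0.5, tol=1e-6).fit(X, y)
        Xd, yd = np.vstack([X, X]), np.r_[y, y]
        b = RBFSupportVectorMachine(C=0.5, gamma=0.5, tol=1e-6).fit(Xd, yd)
        q = rng.normal(size=(20, 2))
        assert np.allclose(a.decision_function(q), b.decision_function(q), atol=5e-3)

    def test_dual_objective_non_decreasing(self, rng):
        X = rng.normal(size=(40, 3))
        y = (rng.random(40) < 0.5).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        m = RBFSupportVectorMachine(record_objective=True).fit(X, y)
        h = np.array(m.dual_objective_history_)
        assert (np.diff(h) >= -1e-9).all()

    def test_deterministic_fit(self, rng):
        X = rng.normal(size=(50, 3))
        y = (rng.random(50) < 0.3).astype(int)
        y[:2] = [0, 1]
        a = RBFSupportVectorMachine().fit(X, y)
        b = RBFSupportVectorMachine().fit(X, y)
        assert np.array_equal(a.dual_coef_, b.dual_coef_) and a.intercept_ == b.intercept_

    def test_box_constraints_respected(self, rng):
        X = rng.normal(size=(60, 3))
        y = (rng.random(60) < 0.2).astype(int)
        y[:2] = [0, 1]
        w = class_weights(y)
        m = RBFSupportVectorMachine(C=2.0).fit(X, y, class_weight=w)
        caps = np.where(m.dual_coef_ > 0, 2.0 * w[1], 2.0 * w[0])
        assert (np.abs(m.dual_coef_) <= caps + 1e-9).all()
        assert m.kkt_gap_ <= m.tol


class TestNeuralNetClassifier:
    def test_zero_init_outputs_half_everywhere(self, rng):
        m = NeuralNetClassifier(epochs=0, zero_init=True)
        m.fit(rng.normal(size=(10, 3)), np.r_[np.zeros(5, int), np.ones(5, int)])
        assert np.allclose(m.predict_score(rng.normal(size=(7, 3))), 0.5)

    def test_forward_pass_matches_hand_computation(self):
        # micro-network 1 -> 2 -> 2 -> 1 with hand-picked weights
        params = [
            np.array([[1.0, -2.0]]), np.array([0.5, 0.25]),
            np.array([[1.0, 0.5], [-1.0, 2.0]]), np.array([0.0, -0.1]),
            np.array([[2.0], [-1.0]]), np.array([0.3]),
        ]
        x = 0.7
        h1 = [max(0.0, 1.0 * x + 0.5), max(0.0, -2.0 * x + 0.25)]  # [1.2, 0]
        h2 = [max(0.0, h1[0] * 1.0 + h1[1] * -1.0 + 0.0),
              max(0.0, h1[0] * 0.5 + h1[1] * 2.0 - 0.1)]  # [1.2, 0.5]
        z = h2[0] * 2.0 + h2[1] * -1.0 + 0.3  # 2.2
        *_, z3 = NeuralNetClassifier._forward(params, np.array([[x]]))
        assert z3[0] == pytest.approx(z, abs=1e-12)
        assert expit(z) == pytest.approx(1 / (1 + np.exp(-2.2)), abs=1e-12)

    def test_backprop_gradient_matches_finite_differences(self, rng):
        X = rng.normal(size=(12, 3))
        y = (rng.random(12) < 0.5).astype(float)
        w = np.where(y == 1, 2.0, 0.7)
        net = NeuralNetClassifier(seed=5)
        params = net._init_params(3)
        _, grads = net._loss_and_grad(params, X, y, w)
        eps = 1e-6
        numeric, analytic = [], []
        for p, g in zip(params, grads):
            for k in {0, p.size - 1, p.size // 2}:
                orig = p.flat[k]
                p.flat[k] = orig + eps
                lp, _ = net._loss_and_grad(params, X, y, w)
                p.flat[k] = orig - eps
                lm, _ = net._loss_and_grad(params, X, y, w)
                p.flat[k] = orig
                numeric.append((lp - lm) / (2 * eps))
                analytic.append(g.flat[k])
        numeric, analytic = np.array(numeric), np.array(analytic)
        rel = np.linalg.norm(numeric - analytic) / np.linalg.norm(analytic)
        assert rel < 1e-6

    def test_loss_non_increasing_with_small_step(self, rng):
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] > 0).astype(int)
        m = NeuralNetClassifier(epochs=150, learning_rate=0.05, seed=2)
        m.fit(X, y)
        assert (np.diff(m.loss_history_) <= 1e-9).all()

    def test_separable_toy_reaches_full_accuracy(self, rng):
        X = np.vstack([rng.normal(-2, 0.5, (20, 2)), rng.normal(2, 0.5, (20, 2))])
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        m = NeuralNetClassifier(epochs=300, learning_rate=0.5, seed=1).fit(X, y)
        assert (((m.predict_score(X) >= 0.5).astype(int)) == y).all()

    def test_output_strictly_inside_unit_interval(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        m = NeuralNetClassifier(epochs=50, seed=0).fit(X, y)
        s = m.predict_score(np.array([[1e4, -1e4], [0.0, 0.0]]))
        assert ((s > 0) & (s < 1)).all()

    def test_sample_order_permutation_same_model(self, rng):
        X = rng.normal(size=(30, 3))
        y = (rng.random(30) < 0.4).astype(int)
        y[:2] = [0, 1]
        w = class_weights(y)
        m1 = NeuralNetClassifier(epochs=80, seed=7).fit(X, y, class_weight=w)
        order = rng.permutation(30)
        m2 = NeuralNetClassifier(epochs=80, seed=7).fit(X[order], y[order], class_weight=w)
        for a, b in zip(m1.params_, m2.params_):
            assert np.allclose(a, b, atol=1e-12)

    def test_non_finite_loss_aborts_with_diagnostic(self, rng):
        X = rng.normal(size=(20, 2))
        X[3, 1] = np.inf  # propagates to a non-finite loss on epoch one
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        m = NeuralNetClassifier(epochs=10, seed=0)
        with pytest.raises(RuntimeError, match="non-finite"):
            m.fit(X, y)


class TestFactoryAndStandardizer:
    def test_factory_names(self):
        assert isinstance(make_classifier("GNB"), GaussianNaiveBayes)
        assert isinstance(make_classifier("SVM"), Standardized)
        assert isinstance(make_classifier("ANN"), Standardized)
        with pytest.raises(ValueError):
            make_classifier("forest")

    def test_standardizer_equivalent_to_manual_scaling(self, rng):
        X = rng.normal(5.0, 3.0, size=(40, 2))
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        wrapped = Standardized(GaussianNaiveBayes()).fit(X, y)
        Xs = (X - X.mean(0)) / X.std(0)
        plain = GaussianNaiveBayes().fit(Xs, y)
        q = rng.normal(5.0, 3.0, size=(10, 2))
        qs = (q - X.mean(0)) / X.std(0)
        assert np.allclose(wrapped.predict_score(q), plain.predict_score(qs))


def test_rbf_kernel_basics(rng):
    A = rng.normal(size=(5, 3))
    K = rbf_kernel(A, A, gamma=0.7)
    assert np.allclose(np.diag(K), 1.0)
    assert np.allclose(K, K.T)
    assert (K > 0).all() and (K <= 1.0).all()
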