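import numpy as np
import pytest

from komet import svm
from komet.exceptions import CalibrationError, ShapeError, TrainingDataError
from komet.svm import TrainingProblem, fit, fit_platt, objective_and_gradient, scores_implicit
from oracles import explicit_objective_grad, explicit_pair_scores


def random_problem(rng, n_M=20, n_P=10, d_M=8, d_P=5, n_Z=100):
    M = rng.standard_normal((n_M, d_M))
    P = rng.standard_normal((n_P, d_P))
    mi = rng.integers(n_M, size=n_Z)
    pj = rng.integers(n_P, size=n_Z)
    y = rng.choice([-1.0, 1.0], size=n_Z)
    return TrainingProblem(M, P, mi, pj, y)


class TestScoresImplicit:
    def test_zero_weights_zero_scores(self, rng):
        pr = random_problem(rng)
        np.testing.assert_array_equal(
            scores_implicit(np.zeros((8, 5)), 0.0, pr), np.zeros(100)
        )

    def test_rank_one_factorization(self, rng):
        pr = random_problem(rng)
        u, v = rng.standard_normal(8), rng.standard_normal(5)
        s = scores_implicit(np.outer(u, v), 0.7, pr)
        expected = (pr.M[pr.mol_idx] @ u) * (pr.P[pr.prot_idx] @ v) + 0.7
        np.testing.assert_allclose(s, expected, rtol=1e-10)

    def test_matches_explicit_kronecker_oracle(self, rng):
        for _ in range(10):
            pr = random_problem(rng)
            W = rng.standard_normal((8, 5))
            b = float(rng.standard_normal())
            s = scores_implicit(W, b, pr)
            se = explicit_pair_scores(W, b, pr.M, pr.P, pr.mol_idx, pr.prot_idx)
            np.testing.assert_allclose(s, se, rtol=1e-10)

    def test_shape_mismatch_raises(self, rng):
        pr = random_problem(rng)
        with pytest.raises(ShapeError):
            scores_implicit(np.zeros((3, 3)), 0.0, pr)


class TestObjectiveGradient:
    def test_origin_closed_form(self, rng):
        pr = random_problem(rng)
        f, gW, gb = objective_and_gradient(np.zeros((8, 5)), 0.0, pr, 0.0)
        assert f == pytest.approx(1.0)
        n_pos = (pr.labels == 1).sum()
        n_neg = (pr.labels == -1).sum()
        assert gb == pytest.approx(-(n_pos - n_neg) / pr.n_Z)

    def test_separated_scores_zero_loss_zero_gradient(self, rng):
        # labels defined by a wide-margin planted scorer
        pr = random_problem(rng, n_Z=50)
        W = rng.standard_normal((8, 5))
        s = scores_implicit(W, 0.0, pr)
        pr2 = TrainingProblem(pr.M, pr.P, pr.mol_idx, pr.prot_idx, np.sign(s))
        W10 = 10.0 * W / np.abs(s).min()  # all margins >= 10
        f, gW, gb = objective_and_gradient(W10, 0.0, pr2, 0.0)
        assert f == 0.0
        np.testing.assert_array_equal(gW, np.zeros((8, 5)))
        assert gb == 0.0

    def test_matches_explicit_oracle(self, rng):
        for _ in range(10):
            pr = random_problem(rng, n_Z=60)
            W = rng.standard_normal((8, 5))
            b = float(rng.standard_normal())
            lam = float(rng.random())
            f, gW, gb = objective_and_gradient(W, b, pr, lam)
            fe, gWe, gbe = explicit_objective_grad(
                W, b, pr.M, pr.P, pr.mol_idx, pr.prot_idx, pr.labels, lam
            )
            assert f == pytest.approx(fe, rel=1e-10)
            np.testing.assert_allclose(gW, gWe, rtol=1e-9, atol=1e-12)
            assert gb == pytest.approx(gbe, rel=1e-10)

    def test_finite_difference_gradient(self, rng):
        pr = random_problem(rng, n_Z=40)
        W = rng.standard_normal((8, 5))
        b = 0.1
        lam = 0.05
        f0, gW, gb = objective_and_gradient(W, b, pr, lam)
        # keep away from hinge kinks: perturbations are tiny
        eps = 1e-6
        for _ in range(10):
            i, j = rng.integers(8), rng.integers(5)
            Wp = W.copy(); Wp[i, j] += eps
            Wm = W.copy(); Wm[i, j] -= eps
            fp, _, _ = objective_and_gradient(Wp, b, pr, lam)
            fm, _, _ = objective_and_gradient(Wm, b, pr, lam)
            assert (fp - fm) / (2 * eps) == pytest.approx(gW[i, j], abs=1e-5)

    def test_swap_symmetry(self, rng):
        pr = random_problem(rng)
        W = rng.standard_normal((8, 5))
        swapped = TrainingProblem(pr.P, pr.M, pr.prot_idx, pr.mol_idx, pr.labels)
        f1, gW1, gb1 = objective_and_gradient(W, 0.2, pr, 0.01)
        f2, gW2, gb2 = objective_and_gradient(W.T, 0.2, swapped, 0.01)
        assert f1 == pytest.approx(f2, rel=1e-12)
        np.testing.assert_allclose(gW2, gW1.T, rtol=1e-10, atol=1e-14)
        assert gb1 == pytest.approx(gb2, rel=1e-12)

    def test_empty_triples_rejected(self, rng):
        pr = TrainingProblem(
            np.zeros((2, 3)), np.zeros((2, 2)),
            np.array([], dtype=int), np.array([], dtype=int), np.array([]),
        )
        with pytest.raises(TrainingDataError):
            objective_and_gradient(np.zeros((3, 2)), 0.0, pr, 0.0)


class TestFit:
    def test_planted_separable_labels_fit_perfectly(self, rng):
        M = rng.standard_normal((10, 4))
        P = rng.standard_normal((5, 3))
        mi = rng.integers(10, size=30)
        pj = rng.integers(5, size=30)
        W_star = np.outer(rng.standard_normal(4), rng.standard_normal(3))
        y = np.sign(
            np.einsum("kd,kd->k", M[mi], (P @ W_star.T)[pj])
        )
        pr = TrainingProblem(M, P, mi, pj, y)
        model = fit(pr, lam=1e-6, max_iter=500)
        pred = np.where(scores_implicit(model.W, model.b, pr) >= 0, 1, -1)
        assert (pred == y).all()

    def test_heavy_regularization_collapses_to_bias(self):
        rng = np.random.default_rng(77)
        pr = random_problem(rng, n_Z=50)
        # imbalanced labels give the bias a well-defined sign once W -> 0
        pr = TrainingProblem(
            pr.M, pr.P, pr.mol_idx, pr.prot_idx,
            np.array([1.0] * 35 + [-1.0] * 15),
        )
        model = fit(pr, lam=1e6)
        assert np.linalg.norm(model.W) <= 1e-3
        s = scores_implicit(model.W, model.b, pr)
        assert (np.sign(s) == np.sign(model.b)).all()

    def test_objective_not_above_origin_value(self, rng):
        pr = random_problem(rng)
        model = fit(pr, lam=1e-3)
        assert model.final_objective <= 1.0 + 1e-12

    def test_deterministic(self, rng):
        pr = random_problem(rng)
        m1 = fit(pr, lam=1e-4)
        m2 = fit(pr, lam=1e-4)
        np.testing.assert_array_equal(m1.W, m2.W)
        assert m1.b == m2.b

    def test_parity_with_reference_linear_svm(self, rng):
        """Final objective within 1e-4 relative of liblinear on explicit
        Kronecker features, with full decision agreement."""
        from sklearn.svm import LinearSVC

        rng = np.random.default_rng(4)
        M = rng.standard_normal((20, 8))
        P = rng.standard_normal((10, 5))
        mi = rng.integers(20, size=100)
        pj = rng.integers(10, size=100)
        W_star = rng.standard_normal((8, 5))
        margins = np.einsum("kd,kd->k", M[mi], (P @ W_star.T)[pj])
        y = np.sign(margins + rng.standard_normal(100))  # non-separable
        pr = TrainingProblem(M, P, mi, pj, y)
        lam = 1e-2
        model = fit(pr, lam=lam, max_iter=5000, tol=1e-12)

        Z = np.stack([np.kron(M[i], P[j]) for i, j in zip(mi, pj)])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # liblinear convergence chatter
            ref = LinearSVC(
                loss="hinge", C=1.0 / (lam * len(y)), intercept_scaling=100.0,
                max_iter=2000000, tol=1e-12,
            ).fit(Z, y)
        W_ref = ref.coef_.reshape(8, 5)
        b_ref = float(ref.intercept_[0])
        f_ours, _, _ = objective_and_gradient(model.W, model.b, pr, lam)
        f_ref, _, _ = objective_and_gradient(W_ref, b_ref, pr, lam)
        assert f_ours <= f_ref * (1 + 1e-4)
        ours = np.where(scores_implicit(model.W, model.b, pr) >= 0, 1, -1)
        theirs = np.where(Z @ W_ref.ravel() + b_ref >= 0, 1, -1)
        assert (ours == theirs).mean() == 1.0


class TestPlatt:
    def test_all_zero_scores_fit_prevalence(self):
        y = np.array([1.0] * 30 + [-1.0] * 10)
        s, t = fit_platt(np.zeros(40), y)
        assert t == pytest.approx(np.log(3.0), abs=1e-6)
        assert 1 / (1 + np.exp(-t)) == pytest.approx(0.75, abs=1e-6)

    def test_perfect_separation_dominates_identity_parameters(self, rng):
        f = np.concatenate([rng.random(20) + 1.0, -rng.random(20) - 1.0])
        y = np.concatenate([np.ones(20), -np.ones(20)])
        s, t = fit_platt(f, y)
        def obj(s_, t_):
            return np.logaddexp(0, -y * (s_ * f + t_)).mean()
        assert obj(s, t) <= obj(1.0, 0.0)
        p = 1 / (1 + np.exp(-(s * np.sort(f) + t)))
        assert (np.diff(p) >= -1e-12).all()

    def test_label_flip_symmetry(self):
        # heavily overlapping classes keep the logistic MLE finite, so the
        # symmetry can be checked to tight tolerance
        rng = np.random.default_rng(55)
        f = rng.standard_normal(200)
        y = np.sign(f + 2.0 * rng.standard_normal(200))
        s1, t1 = fit_platt(f, y)
        s2, t2 = fit_platt(f, -y)
        assert s2 == pytest.approx(-s1, abs=1e-4)
        assert t2 == pytest.approx(-t1, abs=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(CalibrationError):
            fit_platt(np.arange(5.0), np.ones(5))


class TestPredict:
    def test_training_scores_reproduced_bit_exactly(self, rng):
        pr = random_problem(rng, n_Z=40)
        model = fit(pr, lam=1e-4)
        svm.calibrate(model, pr)
        table = svm.predict(model, pr.M, pr.P, pr.mol_idx, pr.prot_idx)
        np.testing.assert_array_equal(
            table.scores, scores_implicit(model.W, model.b, pr)
        )
        assert ((table.probabilities >= 0) & (table.probabilities <= 1)).all()

    def test_platt_scale_preserves_ranking(self, rng):
        pr = random_problem(rng, n_Z=40)
        model = fit(pr, lam=1e-4)
        svm.calibrate(model, pr)
        raw = scores_implicit(model.W, 0.0, pr)
        table = svm.predict(model, pr.M, pr.P, pr.mol_idx, pr.prot_idx)
        if model.platt_s > 0:
            ordered = np.asarray(table.probabilities)[np.argsort(raw)]
            assert (np.diff(ordered) >= -1e-15).all()

    def test_model_serialization_round_trip(self, tmp_path, rng):
        pr = random_problem(rng, n_Z=40)
        model = fit(pr, lam=1e-4)
        svm.calibrate(model, pr)
        path = tmp_path / "model.npz"
        model.save(path)
        back = svm.KometModel.load(path)
        np.testing.assert_array_equal(back.W, model.W)
        assert back.platt_s == model.platt_s
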