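import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvrank.features import FeatureMatrix, impute_and_standardize
from pvrank.model import (
    evaluate_experiment,
    evaluate_split,
    fit_logistic,
    fit_multinomial,
    make_split,
    penalized_loglik,
    predict_proba,
    predict_proba_multinomial,
    roc_auc,
)

# fixed 8-sample toy table used for the grid-search oracle
TOY_X = np.array(
    [
        [0.5, 1.2],
        [-0.3, 0.4],
        [1.5, -0.7],
        [0.1, 0.1],
        [-1.2, -0.5],
        [0.7, 0.9],
        [-0.8, 1.1],
        [0.3, -1.4],
    ]
)
TOY_Y = np.array([1, 0, 1, 0, 0, 1, 0, 1])


def lattice_oracle(X, y, l2_lambda, lo=-2.0, hi=2.0, step=0.01):
    """Exhaustive grid search of the penalized log-likelihood over a lattice."""
    grid = np.round(np.arange(lo, hi + step / 2, step), 10)
    W1, W2 = np.meshgrid(grid, grid, indexing="ij")
    best_ll, best_w = -np.inf, None
    for w0 in grid:
        s = w0 + X[:, 0][:, None, None] * W1 + X[:, 1][:, None, None] * W2
        ll = (y[:, None, None] * s - np.logaddexp(0.0, s)).sum(axis=0)
        ll -= 0.5 * l2_lambda * (W1**2 + W2**2)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        if ll[i, j] > best_ll:
            best_ll, best_w = ll[i, j], np.array([w0, grid[i], grid[j]])
    return best_w, best_ll


def pairwise_auc_oracle(scores, labels):
    """O(n_pos * n_neg) pairwise count with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    sp = scores[labels == 1]
    sn = scores[labels == 0]
    diff = sp[:, None] - sn[None, :]
    return ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(sp) * len(sn))


class TestFitLogistic:
    def test_symmetric_toy_gives_zero_weights(self):
        # x symmetric within each class and prevalence 1/2 force the MLE to 0
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([0, 0, 1, 1])
        fit = fit_logistic(x, y, l2_lambda=0.0, solver="newton")
        assert np.abs(fit.weights).max() < 1e-8
        assert fit.converged

    def test_separable_data_with_penalty_converges(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([0, 0, 1, 1])
        fit = fit_logistic(x, y, l2_lambda=0.5, tol=1e-8)
        assert fit.converged
        assert np.all(np.isfinite(fit.weights))
        assert fit.final_gradient_norm <= 1e-8

    @pytest.mark.parametrize("solver", ["newton", "lbfgs"])
    def test_matches_lattice_oracle(self, solver):
        fit = fit_logistic(TOY_X, TOY_Y, l2_lambda=1.0, tol=1e-10,
                           max_iter=500, solver=solver)
        w_oracle, _ = lattice_oracle(TOY_X, TOY_Y, l2_lambda=1.0, step=0.05)
        assert not np.any(np.isclose(np.abs(w_oracle), 2.0))  # interior optimum
        np.testing.assert_allclose(fit.weights, w_oracle, atol=0.05 + 0.02)

    def test_gradient_norm_at_converged_fit(self, rng):
        X = rng.normal(size=(60, 4))
        y = (rng.random(60) < 0.5).astype(float)
        fit = fit_logistic(X, y, l2_lambda=1.0, tol=1e-9)
        assert fit.converged
        assert fit.final_gradient_norm <= 1e-9

    def test_random_restarts_reach_same_optimum(self, rng):
        # penalized LL is strictly concave for lambda > 0: unique optimum
        X = rng.normal(size=(50, 3))
        y = (rng.random(50) < 0.4).astype(float)
        base = fit_logistic(X, y, l2_lambda=0.7, tol=1e-10)
        for _ in range(3):
            w0 = rng.normal(scale=2.0, size=4)
            alt = fit_logistic(X, y, l2_lambda=0.7, tol=1e-10, w0=w0)
            np.testing.assert_allclose(alt.weights, base.weights, atol=1e-6)

    def test_newton_and_lbfgs_agree(self, rng):
        X = rng.normal(size=(80, 5))
        y = (rng.random(80) < 0.5).astype(float)
        a = fit_logistic(X, y, tol=1e-9, solver="newton")
        b = fit_logistic(X, y, tol=1e-9, max_iter=2000, solver="lbfgs")
        np.testing.assert_allclose(a.weights, b.weights, atol=1e-5)

    def test_warm_start_same_optimum(self, rng):
        X = rng.normal(size=(40, 3))
        y = (rng.random(40) < 0.5).astype(float)
        cold = fit_logistic(X, y, tol=1e-10)
        warm = fit_logistic(X, y, tol=1e-10, w0=cold.weights + 0.5)
        np.testing.assert_allclose(cold.weights, warm.weights, atol=1e-7)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_logistic(np.ones((4, 1)), np.zeros(4))

    def test_nonfinite_X_raises(self):
        with pytest.raises(ValueError, match="non-finite"):
            fit_logistic(np.array([[1.0], [np.nan]]), np.array([0, 1]))

    def test_objective_increases_along_fit(self):
        Xb = np.hstack([np.ones((8, 1)), TOY_X])
        fit = fit_logistic(TOY_X, TOY_Y, l2_lambda=1.0)
        at_zero = penalized_loglik(np.zeros(3), Xb, TOY_Y.astype(float), 1.0)
        at_fit = penalized_loglik(fit.weights, Xb, TOY_Y.astype(float), 1.0)
        assert at_fit > at_zero


class TestPredictProba:
    def test_zero_weights_give_half(self, rng):
        fit = fit_logistic(TOY_X, TOY_Y)
        fit.weights[:] = 0.0
        p = predict_proba(fit, rng.normal(size=(10, 2)))
        np.testing.assert_array_equal(p, 0.5)

    def test_monotone_in_score(self):
        fit = fit_logistic(TOY_X, TOY_Y)
        fit.weights[:] = [0.0, 1.0, 0.0]
        x = np.linspace(-5, 5, 11)[:, None]
        p = predict_proba(fit, np.hstack([x, np.zeros_like(x)]))
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0) & (p < 1))

    def test_dimension_mismatch_raises(self):
        fit = fit_logistic(TOY_X, TOY_Y)
        with pytest.raises(ValueError, match="dimension"):
            predict_proba(fit, np.ones((3, 5)))


class TestMultinomial:
    def test_zero_weights_uniform_over_k3(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.integers(0, 3, size=30)
        fit = fit_multinomial(X, y, l2_lambda=1.0)
        fit.weights[:] = 0.0
        P = predict_proba_multinomial(fit, X)
        np.testing.assert_allclose(P, 1.0 / 3.0, atol=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 4, size=60)
        fit = fit_multinomial(X, y, l2_lambda=1.0)
        P = predict_proba_multinomial(fit, X)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert P.shape == (60, 4)

    def test_k2_reduces_to_binary_logistic(self, rng):
        X = rng.normal(size=(80, 3))
        y = (rng.random(80) < 0.5).astype(int)
        binary = fit_logistic(X, y, l2_lambda=1.0, tol=1e-10)
        multi = fit_multinomial(X, y, l2_lambda=1.0, tol=1e-9, max_iter=2000)
        p_binary = predict_proba(binary, X)
        p_multi = predict_proba_multinomial(multi, X)[:, 1]  # P(class 1)
        np.testing.assert_allclose(p_binary, p_multi, atol=1e-5)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_multinomial(np.ones((4, 1)), np.zeros(4))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_half_concordant_pairs(self):
        # pairs: (.9,.8)+, (.9,.3)+, (.2,.8)-, (.2,.3)- -> 2/4
        assert roc_auc([0.9, 0.2, 0.8, 0.3], [1, 1, 0, 0]) == 0.5

    def test_all_ties_give_half(self):
        assert roc_auc([1.0, 1.0, 1.0, 1.0], [1, 0, 1, 0]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_monotone_transform_invariance(self, rng):
        s = rng.normal(size=100)
        y = (rng.random(100) < 0.5).astype(int)
        assert roc_auc(s, y) == roc_auc(np.exp(s), y)

    def test_complement_identity(self, rng):
        s = rng.integers(0, 5, size=50).astype(float)  # plenty of ties
        y = (rng.random(50) < 0.5).astype(int)
        assert roc_auc(s, y) + roc_auc(s, 1 - y) == pytest.approx(1.0, abs=1e-12)

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_matches_pairwise_oracle(self, data):
        n = data.draw(st.integers(2, 60))
        scores = data.draw(
            st.lists(st.integers(-5, 5), min_size=n, max_size=n).map(
                lambda v: np.asarray(v, dtype=float) / 2.0
            )
        )
        n_pos = data.draw(st.integers(1, n - 1))
        labels = np.zeros(n, dtype=int)
        labels[data.draw(st.permutations(range(n)))[:n_pos]] = 1
        assert roc_auc(scores, labels) == pairwise_auc_oracle(scores, labels)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        s = rng.integers(0, 10, size=200).astype(float)
        y = (rng.random(200) < 0.3).astype(int)
        assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def _feature_matrix(rng, n=120, p=4):
    vals = rng.normal(size=(n, p))
    return FeatureMatrix(
        values=vals,
        columns=[f"c{i}" for i in range(p)],
        stay_ids=[f"s{i}" for i in range(n)],
        pv_set=("HR",),
    )


def _labels(rng, stay_ids, diseases=("D1", "D2")):
    df = pd.DataFrame({"stay_id": stay_ids})
    for d in diseases:
        df[d] = (rng.random(len(stay_ids)) < 0.4).astype(int)
    return df


class TestEvaluate:
    def test_make_split_deterministic_and_partition(self):
        tr1, te1 = make_split(100, 0.7, seed=5)
        tr2, te2 = make_split(100, 0.7, seed=5)
        np.testing.assert_array_equal(tr1, tr2)
        assert len(tr1) == 70 and len(te1) == 30
        assert sorted(np.concatenate([tr1, te1])) == list(range(100))

    def test_bad_split_raises(self):
        with pytest.raises(ValueError):
            make_split(10, 0.0, seed=1)
        with pytest.raises(ValueError):
            make_split(2, 0.9, seed=1)  # rounds to an empty test side

    def test_returns_result_per_disease(self, rng):
        m = _feature_matrix(rng)
        labels = _labels(rng, m.stay_ids)
        results = evaluate_experiment(m, labels, split=(0.7, 1))
        assert [r.disease for r in results] == ["D1", "D2"]
        for r in results:
            assert 0.0 <= r.auc <= 1.0
            assert r.n_pos >= 1 and r.n_neg >= 1

    def test_single_class_disease_reported_with_reason(self, rng):
        m = _feature_matrix(rng)
        labels = _labels(rng, m.stay_ids)
        labels["D2"] = 0
        labels.loc[0, "D2"] = 1  # lone positive: one side of any split lacks it
        results = evaluate_experiment(m, labels, split=(0.7, 1))
        d2 = [r for r in results if r.disease == "D2"][0]
        assert d2.auc is None
        assert d2.reason in ("single_class_train", "single_class_test")

    def test_duplicating_rows_preserves_auc(self, rng):
        # unpenalized MLE is invariant under duplicating every sample, and
        # AUC is a rank statistic, so the held-out AUCs must coincide
        m = _feature_matrix(rng, n=60)
        labels = _labels(rng, m.stay_ids)
        tr, te = make_split(60, 0.5, seed=2)
        std = impute_and_standardize(m, tr)
        kw = dict(l2_lambda=0.0, tol=1e-10, max_iter=500)
        base, _ = evaluate_split(std, labels, tr, te, **kw)

        dup = FeatureMatrix(
            values=np.vstack([m.values, m.values]),
            columns=m.columns,
            stay_ids=m.stay_ids + [s + "_dup" for s in m.stay_ids],
            pv_set=m.pv_set,
        )
        labels2 = pd.concat(
            [labels, labels.assign(stay_id=labels["stay_id"] + "_dup")],
            ignore_index=True,
        )
        tr2 = np.concatenate([tr, tr + 60])
        te2 = np.concatenate([te, te + 60])
        std2 = impute_and_standardize(dup, tr2)
        doubled, _ = evaluate_split(std2, labels2, tr2, te2, **kw)
        for a, b in zip(base, doubled):
            assert a.auc == pytest.approx(b.auc, abs=1e-9)

    def test_unstandardized_matrix_rejected_by_evaluate_split(self, rng):
        m = _feature_matrix(rng)
        labels = _labels(rng, m.stay_ids)
        tr, te = make_split(120, 0.7, seed=0)
        with pytest.raises(ValueError, match="standardized"):
            evaluate_split(m, labels, tr, te)
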