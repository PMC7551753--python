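"""Logistic-regression phenotype classifiers and ROC-AUC evaluation.

The operative model is per-disease one-vs-rest binary logistic regression
(diseases co-occur, so per-disease AUC needs a binary reading); the strict
multinomial form is provided as a variant for single-label inputs.  Fits
maximize the log-likelihood

    L(w) = sum_i [ y_i (w . x_i) - log(1 + exp(w . x_i)) ]

minus a ridge term (lambda/2)||w||^2 on the non-intercept coordinates,
by damped Newton ascent (small problems) or L-BFGS (wide feature
matrices).  Zero-vector initialization makes fits deterministic; the
penalized likelihood is strictly concave for lambda > 0, so the optimum
is unique.

AUC uses the Mann-Whitney rank form with tie correction: the mean over
(positive, negative) pairs of [score_pos > score_neg] + 1/2 [equal].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import rankdata

from .features import FeatureMatrix, impute_and_standardize

__all__ = [
    "ModelFit",
    "MultinomialFit",
    "AUCResult",
    "fit_logistic",
    "predict_proba",
    "fit_multinomial",
    "predict_proba_multinomial",
    "roc_auc",
    "make_split",
    "evaluate_split",
    "evaluate_experiment",
    "penalized_loglik",
]

# feature-count threshold above which the quasi-Newton path is used
# (dense Newton wins comfortably up to ~1000 features on one CPU)
_NEWTON_MAX_FEATURES = 1000


@dataclass
class ModelFit:
    weights: np.ndarray  # intercept first, then one weight per feature
    l2_lambda: float
    converged: bool
    final_gradient_norm: float
    n_iter: int


@dataclass
class MultinomialFit:
    weights: np.ndarray  # (K-1, n_features+1); last class is the reference
    classes: np.ndarray
    l2_lambda: float
    converged: bool
    final_gradient_norm: float
    n_iter: int


@dataclass
class AUCResult:
    disease: str
    pv_set_id: str
    auc: float | None
    n_pos: int
    n_neg: int
    reason: str | None = None


def _design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in feature matrix")
    return np.hstack([np.ones((X.shape[0], 1)), X])


def penalized_loglik(w: np.ndarray, Xb: np.ndarray, y: np.ndarray, l2_lambda: float) -> float:
    """L(w) - (lambda/2)||w[1:]||^2 for a design matrix with intercept column."""
    s = Xb @ w
    # log(1 + exp(s)) computed stably
    ll = float(y @ s - np.sum(np.logaddexp(0.0, s)))
    return ll - 0.5 * l2_lambda * float(w[1:] @ w[1:])


def _grad(w: np.ndarray, Xb: np.ndarray, y: np.ndarray, l2_lambda: float) -> np.ndarray:
    p = expit(Xb @ w)
    g = Xb.T @ (y - p)
    g[1:] -= l2_lambda * w[1:]
    return g


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    l2_lambda: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 200,
    solver: str = "auto",
    w0: np.ndarray | None = None,
) -> ModelFit:
    """Maximize the ridge-penalized log-likelihood (intercept unpenalized).

    ``solver`` is ``"newton"`` (damped Newton with step halving),
    ``"lbfgs"``, or ``"auto"`` (Newton up to 200 features, else L-BFGS).
    Deterministic: starts from the zero vector unless ``w0`` is given.
    """
    y = np.asarray(y, dtype=float).ravel()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("degenerate labels: only one class present")
    if l2_lambda < 0:
        raise ValueError("l2_lambda must be >= 0")
    Xb = _design(X)
    if len(y) != Xb.shape[0]:
        raise ValueError("X and y length mismatch")
    w = np.zeros(Xb.shape[1]) if w0 is None else np.asarray(w0, dtype=float).copy()
    if w.shape != (Xb.shape[1],):
        raise ValueError("w0 dimension mismatch")

    if solver == "auto":
        solver = "newton" if Xb.shape[1] <= _NEWTON_MAX_FEATURES else "lbfgs"
    if solver == "newton":
        return _fit_newton(Xb, y, w, l2_lambda, tol, max_iter)
    if solver == "lbfgs":
        return _fit_lbfgs(Xb, y, w, l2_lambda, tol, max_iter)
    raise ValueError(f"unknown solver {solver!r}")


def _fit_newton(Xb, y, w, l2_lambda, tol, max_iter) -> ModelFit:
    n_iter = 0
    ll = penalized_loglik(w, Xb, y, l2_lambda)
    for n_iter in range(1, max_iter + 1):
        g = _grad(w, Xb, y, l2_lambda)
        gnorm = float(np.linalg.norm(g))
        if gnorm <= tol:
            return ModelFit(w, l2_lambda, True, gnorm, n_iter - 1)
        p = expit(Xb @ w)
        wgt = p * (1.0 - p)
        H = Xb.T @ (Xb * wgt[:, None])
        H[1:, 1:] += l2_lambda * np.eye(Xb.shape[1] - 1)
        H[np.diag_indices_from(H)] += 1e-12  # guards exact singularity at lambda = 0
        step = np.linalg.solve(H, g)
        # backtracking on the (concave) objective
        t = 1.0
        for _ in range(50):
            w_new = w + t * step
            ll_new = penalized_loglik(w_new, Xb, y, l2_lambda)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        w, ll = w_new, ll_new
    g = _grad(w, Xb, y, l2_lambda)
    gnorm = float(np.linalg.norm(g))
    return ModelFit(w, l2_lambda, gnorm <= tol, gnorm, n_iter)


def _fit_lbfgs(Xb, y, w, l2_lambda, tol, max_iter) -> ModelFit:
    def objective(wv):
        return (
            -penalized_loglik(wv, Xb, y, l2_lambda),
            -_grad(wv, Xb, y, l2_lambda),
        )

    res = minimize(
        objective,
        w,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 10 * max_iter, "gtol": tol * 1e-1, "ftol": 0.0},
    )
    g = _grad(res.x, Xb, y, l2_lambda)
    gnorm = float(np.linalg.norm(g))
    return ModelFit(res.x, l2_lambda, gnorm <= tol, gnorm, int(res.nit))


def predict_proba(fit: ModelFit, X: np.ndarray) -> np.ndarray:
    """P(y=1 | x) = logistic(w . x); strictly inside (0, 1)."""
    Xb = _design(X)
    if Xb.shape[1] != fit.weights.shape[0]:
        raise ValueError(
            f"feature dimension mismatch: X gives {Xb.shape[1] - 1}, "
            f"fit expects {fit.weights.shape[0] - 1}"
        )
    p = expit(Xb @ fit.weights)
    tiny = np.finfo(float).tiny
    return np.clip(p, tiny, 1.0 - np.finfo(float).epsneg)


# ---------------------------------------------------------------------------
# multinomial variant (single-label inputs; last class is the reference)


def fit_multinomial(
    X: np.ndarray,
    y: np.ndarray,
    l2_lambda: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MultinomialFit:
    """Softmax MLE with K-1 weight vectors and the last class as reference."""
    y = np.asarray(y).ravel()
    classes = np.unique(y)
    K = len(classes)
    if K < 2:
        raise ValueError("degenerate labels: only one class present")
    Xb = _design(X)
    n, d = Xb.shape
    y_idx = np.searchsorted(classes, y)
    Y = np.zeros((n, K))
    Y[np.arange(n), y_idx] = 1.0

    def scores(Wflat):
        W = Wflat.reshape(K - 1, d)
        s = np.hstack([Xb @ W.T, np.zeros((n, 1))])
        return W, s

    def objective(Wflat):
        W, s = scores(Wflat)
        s_shift = s - s.max(axis=1, keepdims=True)
        logz = np.log(np.exp(s_shift).sum(axis=1)) + s.max(axis=1)
        ll = float(np.sum(s[np.arange(n), y_idx]) - logz.sum())
        pen = 0.5 * l2_lambda * float(np.sum(W[:, 1:] ** 2))
        P = np.exp(s - logz[:, None])
        G = (Y - P)[:, : K - 1].T @ Xb
        G[:, 1:] -= l2_lambda * W[:, 1:]
        return -(ll - pen), -G.ravel()

    res = minimize(
        objective,
        np.zeros((K - 1) * d),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol * 1e-2, "ftol": 0.0},
    )
    gnorm = float(np.linalg.norm(objective(res.x)[1]))
    return MultinomialFit(
        weights=res.x.reshape(K - 1, d),
        classes=classes,
        l2_lambda=l2_lambda,
        converged=gnorm <= tol,
        final_gradient_norm=gnorm,
        n_iter=int(res.nit),
    )


def predict_proba_multinomial(fit: MultinomialFit, X: np.ndarray) -> np.ndarray:
    """K class probabilities per row, summing to 1."""
    Xb = _design(X)
    if Xb.shape[1] != fit.weights.shape[1]:
        raise ValueError("feature dimension mismatch")
    s = np.hstack([Xb @ fit.weights.T, np.zeros((Xb.shape[0], 1))])
    s -= s.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# ROC-AUC


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney AUC.

    Equals the mean over (pos, neg) pairs of ``[s_pos > s_neg] + 1/2
    [s_pos == s_neg]``; invariant under strictly monotone transforms of
    the scores.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels length mismatch")
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks give the half-credit tie correction
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# experiment evaluation


def make_split(n: int, train_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stay-level train/held-out split (deterministic permutation)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(round(n * train_fraction))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves one side empty")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _align_labels(labels: pd.DataFrame, stay_ids: list[str]) -> pd.DataFrame:
    lab = labels.set_index(labels["stay_id"].astype(str))
    missing = [s for s in stay_ids if s not in lab.index]
    if missing:
        raise ValueError(f"stays without a label row: {missing[:5]} (n={len(missing)})")
    return lab.loc[[str(s) for s in stay_ids]]


def evaluate_split(
    matrix: FeatureMatrix,
    labels: pd.DataFrame,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    diseases: list[str] | None = None,
    pv_set_id: str = "all",
    l2_lambda: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 200,
    solver: str = "auto",
    warm_starts: dict[str, np.ndarray] | None = None,
) -> tuple[list[AUCResult], dict[str, ModelFit]]:
    """Fit one one-vs-rest classifier per disease; score the held-out rows.

    ``matrix`` must already be imputed/standardized (``scaler`` set).
    Diseases with a single class on either side are reported with a
    reason instead of an AUC.
    """
    if matrix.scaler is None:
        raise ValueError("matrix must be imputed/standardized before fitting")
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ValueError("split leaves one side empty")
    lab = _align_labels(labels, matrix.stay_ids)
    if diseases is None:
        diseases = [c for c in labels.columns if c != "stay_id"]

    X = matrix.values
    results: list[AUCResult] = []
    fits: dict[str, ModelFit] = {}
    for disease in diseases:
        y = lab[disease].to_numpy(dtype=float)
        y_tr, y_te = y[train_idx], y[test_idx]
        n_pos, n_neg = int(y_te.sum()), int(len(y_te) - y_te.sum())
        if y_tr.min() == y_tr.max():
            results.append(AUCResult(disease, pv_set_id, None, n_pos, n_neg, "single_class_train"))
            continue
        if y_te.min() == y_te.max():
            results.append(AUCResult(disease, pv_set_id, None, n_pos, n_neg, "single_class_test"))
            continue
        w0 = warm_starts.get(disease) if warm_starts else None
        fit = fit_logistic(
            X[train_idx], y_tr, l2_lambda=l2_lambda, tol=tol, max_iter=max_iter,
            solver=solver, w0=w0,
        )
        fits[disease] = fit
        auc = roc_auc(predict_proba(fit, X[test_idx]), y_te)
        results.append(AUCResult(disease, pv_set_id, auc, n_pos, n_neg))
    return results, fits


def evaluate_experiment(
    matrix: FeatureMatrix,
    labels: pd.DataFrame,
    split: tuple[float, int] = (0.7, 0),
    diseases: list[str] | None = None,
    l2_lambda: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 200,
    solver: str = "auto",
) -> list[AUCResult]:
    """One full experiment: split, standardize on train rows, fit, score."""
    train_fraction, seed = split
    train_idx, test_idx = make_split(len(matrix.stay_ids), train_fraction, seed)
    if matrix.scaler is None:
        matrix = impute_and_standardize(matrix, train_idx)
    results, _ = evaluate_split(
        matrix, labels, train_idx, test_idx, diseases=diseases,
        l2_lambda=l2_lambda, tol=tol, max_iter=max_iter, solver=solver,
    )
    return results
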