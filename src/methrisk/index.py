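"""Penalized methylation risk index.

Ridge- or lasso-penalized logistic classifiers are trained on the top-ranked
CpGs; the regularisation strength is chosen by K-fold cross-validated
binomial deviance over a geometric grid anchored at the data-driven maximum
lambda.  The finalised index is the linear score

    index = (sum_i w_i x_i - mu) / sigma

over the selected CpG beta values x_i, where mu and sigma are the mean and
standard deviation of sum_i w_i x_i in the training data — i.e. the index has
zero mean and unit SD in training, and is exactly linear in the betas.  The
classifier intercept is excluded from the sum (it cancels under the scaling).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "IndexModel",
    "train_penalized_classifier",
    "sweep_index_size",
    "finalize_index",
    "compute_index",
    "subclassifier_analysis",
    "PenalizedMethylationIndex",
]

_PENALTIES = {"ridge": "l2", "lasso": "l1"}


@dataclass
class IndexModel:
    """A finalised, serialisable methylation index."""

    cpgs: list
    weights: list
    mu: float
    sigma: float
    n: int
    penalty: str
    lambda_: float
    seed: int
    training_means: list  # per-CpG training mean betas, for scoring-time imputation
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not len(self.weights) == len(self.cpgs) == self.n:
            raise ValueError("weights, cpgs and n must agree")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "IndexModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int, lambda_min_ratio: float):
    """Geometric grid from the data-driven maximum down to a small fraction of it.

    The anchor is max_j |x_j'(y - ybar)| / n — the smallest lambda at which a
    lasso fit is fully sparse; it serves as a scale anchor for ridge too.
    """
    resid = y - y.mean()
    lmax = float(np.abs(X.T @ resid).max() / len(y))
    if lmax <= 0:
        lmax = 1.0
    return np.geomspace(lmax, lmax * lambda_min_ratio, n_lambdas)


def _fit_path(X, y, lambdas, penalty, tol=1e-6, max_iter=2000):
    """Fit a warm-started logistic path over decreasing lambda.

    Returns arrays of coefficients (len(lambdas) x p) and intercepts.
    sklearn's C maps to 1 / (n * lambda).
    """
    n = len(y)
    l1 = _PENALTIES[penalty] == "l1"
    solver = "liblinear" if l1 else "lbfgs"
    clf = LogisticRegression(
        l1_ratio=1.0 if l1 else 0.0, C=1.0, solver=solver, warm_start=not l1,
        tol=tol, max_iter=max_iter,
    )
    coefs = np.zeros((len(lambdas), X.shape[1]))
    icepts = np.zeros(len(lambdas))
    for i, lam in enumerate(lambdas):
        clf.set_params(C=1.0 / (n * lam))
        clf.fit(X, y)
        coefs[i] = clf.coef_[0]
        icepts[i] = clf.intercept_[0]
    return coefs, icepts


def _as_binary(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype.kind in "OUS":
        return (lab == "case").astype(int)
    return lab.astype(int)


def train_penalized_classifier(
    train_beta: pd.DataFrame,
    labels,
    ranked_cpgs,
    n: int,
    penalty: str = "ridge",
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-4,
    lambda_rule: str = "min",
) -> dict:
    """Cross-validated penalized logistic fit on the top-``n`` ranked CpGs.

    Lambda is selected by mean out-of-fold binomial deviance over a geometric
    grid (ties resolve to the stronger penalty); ``lambda_rule='1se'``
    instead takes the strongest penalty within one standard error of the
    minimum (the usual parsimony rule for sparse fits).  Folds are stratified
    so both classes appear in every fold, and the whole procedure is
    deterministic given ``seed``.  Returns a dict with ``cpgs, weights,
    intercept, lambda_, cv_deviance, lambdas``.
    """
    if penalty not in _PENALTIES:
        raise ValueError(f"penalty must be one of {sorted(_PENALTIES)}")
    ranked_cpgs = list(ranked_cpgs)
    if n > len(ranked_cpgs):
        raise ValueError(f"n={n} exceeds the ranked list length {len(ranked_cpgs)}")
    cpgs = ranked_cpgs[:n]
    y = _as_binary(pd.Series(labels).reindex(train_beta.columns).to_numpy())
    X = train_beta.loc[cpgs].to_numpy().T
    lambdas = _lambda_grid(X, y, n_lambdas, lambda_min_ratio)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, len(lambdas)))
    for f, (tr, va) in enumerate(skf.split(X, y)):
        coefs, icepts = _fit_path(X[tr], y[tr], lambdas, penalty)
        eta = X[va] @ coefs.T + icepts  # n_va x n_lambda
        prob = 1.0 / (1.0 + np.exp(-eta))
        for i in range(len(lambdas)):
            dev[f, i] = 2 * log_loss(y[va], prob[:, i], labels=[0, 1])
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))  # grid is descending: ties keep stronger penalty
    if lambda_rule == "1se":
        se = dev.std(axis=0, ddof=1) / np.sqrt(folds)
        within = np.nonzero(mean_dev <= mean_dev[best] + se[best])[0]
        best = int(within[0])  # largest lambda within one SE
    elif lambda_rule != "min":
        raise ValueError("lambda_rule must be 'min' or '1se'")
    lam = float(lambdas[best])
    coefs, icepts = _fit_path(X, y, lambdas[: best + 1], penalty)
    return {
        "cpgs": cpgs,
        "weights": coefs[best],
        "intercept": float(icepts[best]),
        "lambda_": lam,
        "cv_deviance": mean_dev,
        "lambdas": lambdas,
    }


def _linear_score(beta: pd.DataFrame, cpgs, weights) -> np.ndarray:
    return beta.loc[list(cpgs)].to_numpy().T @ np.asarray(weights)


def sweep_index_size(
    train_beta: pd.DataFrame,
    train_labels,
    val_beta: pd.DataFrame,
    val_labels,
    ranked_cpgs,
    n_grid,
    penalty: str = "ridge",
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-4,
):
    """Validation AUC as a function of the number of top-ranked CpGs.

    One classifier is trained per grid value (lambda re-tuned each time);
    the optimum maximises validation AUC, with ties resolved to the smallest
    n.  Train and validation samples must be disjoint.  Returns
    ``(table, optimal_n, fit_at_optimum)``.
    """
    n_grid = sorted(set(int(n) for n in n_grid))
    if not n_grid:
        raise ValueError("n_grid is empty")
    if set(train_beta.columns) & set(val_beta.columns):
        raise ValueError("train and validation samples overlap")
    y_val = _as_binary(pd.Series(val_labels).reindex(val_beta.columns).to_numpy())
    rows, fits = [], {}
    for n in n_grid:
        fit = train_penalized_classifier(
            train_beta, train_labels, ranked_cpgs, n, penalty=penalty, folds=folds,
            seed=seed, n_lambdas=n_lambdas, lambda_min_ratio=lambda_min_ratio,
        )
        score = _linear_score(val_beta, fit["cpgs"], fit["weights"])
        rows.append({"n": n, "auc_validation": float(roc_auc_score(y_val, score)),
                     "lambda_": fit["lambda_"]})
        fits[n] = fit
    table = pd.DataFrame(rows)
    optimal_n = int(table.loc[table["auc_validation"].idxmax(), "n"])  # first max = smallest n
    return table, optimal_n, fits[optimal_n]


def finalize_index(
    discovery_beta: pd.DataFrame,
    labels,
    ranked_cpgs,
    n: int,
    penalty: str,
    lambda_: float,
    seed: int = 0,
) -> IndexModel:
    """Refit on the full discovery set at fixed lambda and scale the index.

    mu and sigma are the mean and SD (ddof=1) of sum_i w_i x_i over the refit
    training samples, so the training-set index has mean 0 and SD 1.
    """
    cpgs = list(ranked_cpgs)[:n]
    y = _as_binary(pd.Series(labels).reindex(discovery_beta.columns).to_numpy())
    X = discovery_beta.loc[cpgs].to_numpy().T
    coefs, icepts = _fit_path(X, y, [lambda_], penalty)
    w = coefs[0]
    s = X @ w
    mu, sigma = float(s.mean()), float(s.std(ddof=1))
    if sigma == 0:
        raise ValueError("degenerate index: training scores have zero variance")
    return IndexModel(
        cpgs=cpgs, weights=w.tolist(), mu=mu, sigma=sigma, n=n, penalty=penalty,
        lambda_=float(lambda_), seed=seed, training_means=X.mean(axis=0).tolist(),
        intercept=float(icepts[0]),
    )


def compute_index(model: IndexModel, beta: pd.DataFrame, min_overlap: float = 0.95) -> pd.Series:
    """Score samples: (sum_i w_i x_i - mu) / sigma, in training-SD units.

    Model CpGs missing from the matrix (at most ``1 - min_overlap`` of them)
    are imputed at the training mean beta.
    """
    present = [c for c in model.cpgs if c in beta.index]
    if len(present) < min_overlap * len(model.cpgs):
        raise ValueError(
            f"only {len(present)}/{len(model.cpgs)} index CpGs present (< {min_overlap:.0%})"
        )
    X = pd.DataFrame(index=model.cpgs, columns=beta.columns, dtype=float)
    X.loc[present] = beta.loc[present].to_numpy()
    means = pd.Series(model.training_means, index=model.cpgs)
    missing = X.index.difference(present)
    if len(missing):
        X.loc[missing] = np.broadcast_to(
            means.loc[missing].to_numpy()[:, None], (len(missing), X.shape[1])
        )
    s = X.to_numpy().T @ np.asarray(model.weights)
    return pd.Series((s - model.mu) / model.sigma, index=beta.columns, name="index")


def subclassifier_analysis(
    model: IndexModel,
    train_beta: pd.DataFrame,
    train_labels,
    val_beta: pd.DataFrame,
    val_labels,
    top_ns=(100, 500, 1000, 3000),
    bin_size: int = 500,
    folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 30,
) -> dict:
    """AUCs of fresh classifiers on weight-ranked subsets of the index CpGs.

    Index CpGs are ranked by |weight| descending; for each condition (top-n
    retained, top-n removed, consecutive bins of ``bin_size``) a new
    classifier is trained on that subset and evaluated on validation.
    """
    order = np.argsort(-np.abs(np.asarray(model.weights)), kind="stable")
    ranked = [model.cpgs[i] for i in order]
    y_val = _as_binary(pd.Series(val_labels).reindex(val_beta.columns).to_numpy())

    def _auc_on(subset):
        fit = train_penalized_classifier(
            train_beta, train_labels, subset, len(subset), penalty=model.penalty,
            folds=folds, seed=seed, n_lambdas=n_lambdas,
        )
        score = _linear_score(val_beta, fit["cpgs"], fit["weights"])
        return float(roc_auc_score(y_val, score))

    retained, removed = [], []
    for n in top_ns:
        n = min(n, len(ranked))
        retained.append({"n": n, "auc": _auc_on(ranked[:n])})
        if n < len(ranked):
            removed.append({"n": n, "auc": _auc_on(ranked[n:])})
    bins = []
    if bin_size >= len(ranked):
        bins.append({"bin": 0, "start": 0, "auc": _auc_on(ranked)})
    else:
        for b, start in enumerate(range(0, len(ranked) - bin_size + 1, bin_size)):
            bins.append({"bin": b, "start": start, "auc": _auc_on(ranked[start:start + bin_size])})
    return {
        "retained": pd.DataFrame(retained),
        "removed": pd.DataFrame(removed),
        "bins": pd.DataFrame(bins),
    }


class PenalizedMethylationIndex(BaseEstimator, ClassifierMixin):
    """Penalized logistic methylation index as a scikit-learn classifier.

    ``X`` is samples x CpGs with columns already in ranking order (use
    :func:`methrisk.dmp.rank_cpgs` upstream); ``n_cpgs`` truncates to the top
    of that order.  After ``fit``, ``decision_function`` returns the scaled
    index (training mean 0, SD 1) and ``predict_proba`` the logistic
    case probability.

    Attributes
    ----------
    model_ : IndexModel
    weights_, mu_, sigma_, lambda_ : fitted index parameters
    classes_ : ndarray of the two class labels
    """

    def __init__(self, n_cpgs=None, penalty="ridge", folds=10, n_lambdas=100,
                 lambda_min_ratio=1e-4, random_state=0):
        self.n_cpgs = n_cpgs
        self.penalty = penalty
        self.folds = folds
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.random_state = random_state

    def _to_frame(self, X):
        if isinstance(X, pd.DataFrame):
            return X.T  # CpG x sample
        X = np.asarray(X, dtype=float)
        cols = [f"f{i}" for i in range(X.shape[1])]
        return pd.DataFrame(X.T, index=cols,
                            columns=[f"s{i}" for i in range(X.shape[0])])

    def fit(self, X, y):
        beta = self._to_frame(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary classification only")
        y01 = (y == self.classes_[1]).astype(int)
        labels = pd.Series(y01, index=beta.columns)
        n = self.n_cpgs or beta.shape[0]
        fit = train_penalized_classifier(
            beta, labels, list(beta.index), n, penalty=self.penalty, folds=self.folds,
            seed=self.random_state, n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
        )
        self.model_ = finalize_index(
            beta, labels, list(beta.index), n, self.penalty, fit["lambda_"],
            seed=self.random_state,
        )
        self.weights_ = np.asarray(self.model_.weights)
        self.intercept_ = self.model_.intercept
        self.mu_, self.sigma_ = self.model_.mu, self.model_.sigma
        self.lambda_ = self.model_.lambda_
        self.cpgs_ = list(self.model_.cpgs)
        return self

    def decision_function(self, X):
        beta = self._to_frame(X)
        return compute_index(self.model_, beta).to_numpy()

    def predict_proba(self, X):
        beta = self._to_frame(X)
        eta = _linear_score(beta, self.cpgs_, self.weights_) + self.intercept_
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] > 0.5).astype(int)]
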