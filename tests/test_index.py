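"""Penalized index training, size sweep, scaling, scoring, sub-classifiers."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import cross_val_predict

from methrisk.dmp import estimate_delta_betas, rank_cpgs
from methrisk.index import (
    IndexModel,
    PenalizedMethylationIndex,
    compute_index,
    finalize_index,
    subclassifier_analysis,
    sweep_index_size,
    train_penalized_classifier,
)


def _noise_cohort(n=200, p=100, seed=0):
    rng = np.random.default_rng(seed)
    beta = pd.DataFrame(
        rng.beta(4, 4, (p, n)),
        index=pd.Index([f"cg{i:04d}" for i in range(p)], name="cpg_id"),
        columns=[f"s{i}" for i in range(n)],
    )
    labels = pd.Series(rng.permutation([1] * (n // 2) + [0] * (n // 2)), index=beta.columns)
    return beta, labels


def test_separable_data_training_auc_one():
    beta = pd.DataFrame(
        {"s%d" % i: ([0.9, 0.1] if i < 10 else [0.1, 0.9]) for i in range(20)},
        index=pd.Index(["cgA", "cgB"], name="cpg_id"),
    )
    labels = pd.Series([1] * 10 + [0] * 10, index=beta.columns)
    fit = train_penalized_classifier(beta, labels, ["cgA", "cgB"], 2, "ridge",
                                     folds=5, seed=0, n_lambdas=20)
    score = beta.to_numpy().T @ fit["weights"]
    assert roc_auc_score(labels, score) == 1.0


def test_null_cross_validated_auc_near_half():
    beta, labels = _noise_cohort(seed=1)
    est = PenalizedMethylationIndex(penalty="ridge", folds=3, n_lambdas=10, random_state=0)
    scores = cross_val_predict(est, beta.T, labels.to_numpy(), cv=5, method="decision_function")
    auc = roc_auc_score(labels, scores)
    assert 0.4 <= auc <= 0.6


def test_lasso_support_recovery():
    """1,000 CpGs, 20 informative: lasso finds all of them and they dominate the weights."""
    rng = np.random.default_rng(50)
    n, p, k = 300, 1000, 20
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
    X = np.clip(rng.beta(4, 4, (p, n)) + np.where(
        (np.arange(p) < k)[:, None] & (y == 1)[None, :], 0.25, 0.0), 0, 1)
    beta = pd.DataFrame(X, index=pd.Index([f"cg{i:04d}" for i in range(p)], name="cpg_id"),
                        columns=[f"s{i}" for i in range(n)])
    labels = pd.Series(y, index=beta.columns)
    fit = train_penalized_classifier(
        beta, labels, list(beta.index), p, "lasso", folds=10, seed=0,
        n_lambdas=30, lambda_min_ratio=0.01, lambda_rule="1se",
    )
    w = np.abs(fit["weights"])
    assert np.count_nonzero(w[:k]) == k
    assert w[:k].sum() >= 0.5 * w.sum()


def test_n_exceeding_ranked_list_errors():
    beta, labels = _noise_cohort(n=40, p=10)
    with pytest.raises(ValueError, match="exceeds"):
        train_penalized_classifier(beta, labels, list(beta.index), 11, "ridge", folds=3)
    with pytest.raises(ValueError, match="penalty"):
        train_penalized_classifier(beta, labels, list(beta.index), 5, "elastic", folds=3)


@pytest.fixture(scope="module")
def planted_split(cohort_small):
    beta, sheet, _, truth = cohort_small
    labels = sheet.set_index("sample_id")["type"]
    rng = np.random.default_rng(70)
    ids = rng.permutation(beta.columns.to_numpy())
    train, val = list(ids[:130]), list(ids[130:])
    rec = estimate_delta_betas(beta[train], truth.fractions["immune"][train], labels[train])
    ranked = rank_cpgs(rec)
    return beta, labels, train, val, ranked, truth


def test_sweep_coverage_and_tie_rules(planted_split):
    beta, labels, train, val, ranked, truth = planted_split
    table, opt_n, fit = sweep_index_size(
        beta[train], labels[train], beta[val], labels[val], ranked, [20, 60, 120],
        penalty="ridge", folds=4, seed=0, n_lambdas=10,
    )
    aucs = table.set_index("n")["auc_validation"]
    assert aucs[60] >= aucs[20] - 0.02  # covering all planted CpGs cannot hurt
    assert opt_n in table["n"].values
    t1, n1, _ = sweep_index_size(
        beta[train], labels[train], beta[val], labels[val], ranked, [60],
        penalty="ridge", folds=4, seed=0, n_lambdas=10,
    )
    assert n1 == 60 and len(t1) == 1
    with pytest.raises(ValueError, match="empty"):
        sweep_index_size(beta[train], labels[train], beta[val], labels[val], ranked, [],
                         penalty="ridge")
    with pytest.raises(ValueError, match="overlap"):
        sweep_index_size(beta[train], labels[train], beta[train], labels[train], ranked, [20],
                         penalty="ridge")


def test_finalize_deterministic_scaled_and_roundtrip(tmp_path, planted_split):
    beta, labels, train, val, ranked, _ = planted_split
    m1 = finalize_index(beta, labels, ranked, 60, "ridge", 0.05, seed=3)
    m2 = finalize_index(beta, labels, ranked, 60, "ridge", 0.05, seed=3)
    assert m1.weights == m2.weights
    idx = compute_index(m1, beta)
    assert idx.mean() == pytest.approx(0.0, abs=1e-8)
    assert idx.std(ddof=1) == pytest.approx(1.0, abs=1e-8)
    path = tmp_path / "model.json"
    m1.to_json(path)
    m3 = IndexModel.from_json(path)
    pd.testing.assert_series_equal(compute_index(m3, beta), idx)


def test_compute_index_hand_arithmetic():
    model = IndexModel(cpgs=["c1", "c2"], weights=[1.0, -1.0], mu=0.0, sigma=0.5,
                       n=2, penalty="ridge", lambda_=0.1, seed=0, training_means=[0.5, 0.5])
    beta = pd.DataFrame({"s": [0.8, 0.3]}, index=pd.Index(["c1", "c2"], name="cpg_id"))
    assert compute_index(model, beta)["s"] == pytest.approx(1.0, abs=1e-12)
    at_mu = pd.DataFrame({"s": [0.6, 0.6]}, index=pd.Index(["c1", "c2"], name="cpg_id"))
    assert compute_index(model, at_mu)["s"] == pytest.approx(0.0, abs=1e-12)


def test_compute_index_linearity(planted_split):
    beta, labels, train, val, ranked, _ = planted_split
    model = finalize_index(beta, labels, ranked, 40, "ridge", 0.05, seed=0)
    b1, b2 = beta[train[:10]], beta[train[10:20]].set_axis(beta[train[:10]].columns, axis=1)
    rho = 0.3
    lhs = compute_index(model, (1 - rho) * b1 + rho * b2)
    rhs = (1 - rho) * compute_index(model, b1) + rho * compute_index(model, b2)
    np.testing.assert_allclose(lhs, rhs, atol=1e-10)


def test_compute_index_missing_cpg_policy(planted_split):
    beta, labels, train, val, ranked, _ = planted_split
    model = finalize_index(beta, labels, ranked, 60, "ridge", 0.05, seed=0)
    drop2 = beta.drop(index=model.cpgs[:2])  # 96.7% overlap: imputed at training means
    scores = compute_index(model, drop2)
    assert np.isfinite(scores).all()
    with pytest.raises(ValueError, match="present"):
        compute_index(model, beta.drop(index=model.cpgs[:10]))


def test_ridge_weights_shrink_with_lambda(planted_split):
    beta, labels, train, val, ranked, _ = planted_split
    norms = []
    for lam in (0.01, 0.1, 1.0, 10.0):
        m = finalize_index(beta, labels, ranked, 30, "ridge", lam, seed=0)
        norms.append(np.linalg.norm(m.weights))
    assert norms == sorted(norms, reverse=True)


def test_subclassifier_retaining_all_matches_full_model(planted_split):
    beta, labels, train, val, ranked, _ = planted_split
    model = finalize_index(beta[train], labels[train], ranked, 60, "ridge", 0.05, seed=0)
    res = subclassifier_analysis(
        model, beta[train], labels[train], beta[val], labels[val],
        top_ns=(60,), bin_size=60, folds=3, seed=0, n_lambdas=8,
    )
    full = train_penalized_classifier(beta[train], labels[train], model.cpgs, 60, "ridge",
                                      folds=3, seed=0, n_lambdas=8)
    score = beta[val].loc[full["cpgs"]].to_numpy().T @ full["weights"]
    full_auc = roc_auc_score((labels[val] == "case").astype(int), score)
    assert res["retained"].loc[0, "auc"] == pytest.approx(full_auc, abs=1e-12)
    assert res["removed"].empty
    assert len(res["bins"]) == 1


def test_sklearn_estimator_contract(planted_split):
    beta, labels, train, val, ranked, _ = planted_split
    est = PenalizedMethylationIndex(n_cpgs=30, penalty="ridge", folds=3, n_lambdas=8,
                                    random_state=1)
    params = est.get_params()
    assert params["n_cpgs"] == 30
    est2 = clone(est).set_params(n_cpgs=20)
    assert est2.get_params()["n_cpgs"] == 20
    X = beta.loc[ranked[:30], train].T
    y = (labels[train] == "case").astype(int).to_numpy()
    est.fit(X, y)
    assert len(est.weights_) == 30 and est.sigma_ > 0
    dec = est.decision_function(X)
    assert dec.mean() == pytest.approx(0.0, abs=1e-8)
    proba = est.predict_proba(X)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
    assert set(est.predict(X)) <= set(est.classes_)
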