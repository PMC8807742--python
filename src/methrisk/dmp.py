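"""Cell-type-resolved differential methylation.

In a heterogeneous smear the case/control methylation difference carried by
epithelial cells is diluted in samples with a high immune-cell (IC) fraction.
The intercept method recovers compartment-level delta-betas: per CpG, beta is
regressed linearly on IC within cases and within controls separately; the
difference of the two regression lines at IC = 0 estimates the epithelial
delta-beta and the difference at IC = 1 the immune delta-beta.  The module
also ranks CpGs by those deltas and runs the covariate-adjusted per-CpG
association scan (beta ~ label + IC + age) with Bonferroni correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = ["estimate_delta_betas", "rank_cpgs", "dmp_association_test", "InterceptDeltaBeta"]


def _group_lines(B: np.ndarray, t: np.ndarray):
    """Per-CpG OLS slope/intercept of beta on IC for one group (vectorised)."""
    tbar = t.mean()
    dt = t - tbar
    denom = float(dt @ dt)
    if denom == 0:
        return None, None
    slope = (B @ dt) / denom
    intercept = B.mean(axis=1) - slope * tbar
    return intercept, slope


def estimate_delta_betas(beta: pd.DataFrame, ic, labels) -> pd.DataFrame:
    """Epithelial and immune delta-betas by the intercept method.

    ``ic`` is the per-sample immune fraction, ``labels`` the case/control
    assignment ('case' counts as case; any other value as control).  Both are
    aligned to the columns of ``beta``.  Each group needs >= 3 samples and a
    non-degenerate IC spread; a degenerate group yields a table flagged
    unavailable rather than silent zeros.
    """
    ic = pd.Series(ic).reindex(beta.columns).to_numpy(dtype=float)
    lab = pd.Series(labels).reindex(beta.columns).to_numpy()
    is_case = lab == "case" if lab.dtype.kind in "OUS" else lab.astype(bool)
    if is_case.sum() < 3 or (~is_case).sum() < 3:
        raise ValueError("need at least 3 cases and 3 controls")
    B = beta.to_numpy()
    out = pd.DataFrame(index=beta.index.copy())
    ci, cs = _group_lines(B[:, is_case], ic[is_case])
    ki, ks = _group_lines(B[:, ~is_case], ic[~is_case])
    if ci is None or ki is None:
        for col in ("case_intercept", "case_slope", "control_intercept", "control_slope",
                    "epithelial_delta", "immune_delta"):
            out[col] = np.nan
        out["available"] = False
        return out
    out["case_intercept"], out["case_slope"] = ci, cs
    out["control_intercept"], out["control_slope"] = ki, ks
    out["epithelial_delta"] = ci - ki
    out["immune_delta"] = (ci + cs) - (ki + ks)
    out["available"] = True
    return out


def rank_cpgs(records: pd.DataFrame, mode: str = "epithelial") -> list:
    """CpG ids ordered by descending absolute delta of the chosen compartment.

    ``combined`` ranks by the larger of the two absolute deltas.  Ties are
    broken lexicographically by CpG id.
    """
    if len(records) == 0:
        raise ValueError("records table is empty")
    if mode == "epithelial":
        key = records["epithelial_delta"].abs()
    elif mode == "immune":
        key = records["immune_delta"].abs()
    elif mode == "combined":
        key = np.maximum(records["epithelial_delta"].abs(), records["immune_delta"].abs())
    else:
        raise ValueError(f"unknown ranking mode '{mode}'")
    df = pd.DataFrame({"key": key.to_numpy(), "cpg": records.index.to_numpy()})
    df = df.sort_values(["key", "cpg"], ascending=[False, True], kind="mergesort")
    return df["cpg"].tolist()


def dmp_association_test(beta: pd.DataFrame, labels, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-CpG linear-model scan: beta ~ label + covariates.

    Returns a table with the two-sided p-value for the label coefficient and
    its Bonferroni adjustment (multiplier = number of CpGs tested).  CpGs
    with zero residual variance (e.g. constant betas) are flagged with NaN
    p-values rather than dropped.
    """
    lab = pd.Series(labels).reindex(beta.columns).to_numpy()
    y01 = (lab == "case").astype(float) if lab.dtype.kind in "OUS" else lab.astype(float)
    cov = covariates.reindex(beta.columns)
    if cov.isna().any().any():
        raise ValueError("covariates must be complete for all samples")
    X = np.column_stack([np.ones(len(y01)), y01, cov.to_numpy(dtype=float)])
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient (collinear covariates)")
    B = beta.to_numpy().T  # samples x cpgs
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ X.T @ B  # p x cpgs
    resid = B - X @ coef
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    sigma2[sigma2 < 1e-20] = 0.0  # numerically-zero residual variance: degenerate CpG
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, coef[1] / se, np.nan)
    pval = 2 * stats.t.sf(np.abs(tval), dof)
    m = beta.shape[0]
    out = pd.DataFrame(
        {
            "effect": coef[1],
            "p": pval,
            "p_bonferroni": np.minimum(pval * m, 1.0),
            "available": np.isfinite(tval),
        },
        index=beta.index.copy(),
    )
    return out


class InterceptDeltaBeta(BaseEstimator):
    """Scikit-learn-style wrapper around the intercept method.

    ``fit(X, y, ic=...)`` takes a CpG x sample beta DataFrame, case/control
    labels and the per-sample immune fractions; fitted delta-beta records are
    available as ``records_`` and a ranking via :meth:`ranking`.
    """

    def __init__(self, mode: str = "epithelial"):
        self.mode = mode

    def fit(self, X: pd.DataFrame, y, ic=None):
        if ic is None:
            raise ValueError("fit requires the per-sample immune fraction via ic=")
        self.records_ = estimate_delta_betas(X, ic, y)
        return self

    def ranking(self) -> list:
        if not hasattr(self, "records_"):
            raise RuntimeError("InterceptDeltaBeta is not fitted")
        return rank_cpgs(self.records_, mode=self.mode)
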