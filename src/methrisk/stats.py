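"""Evaluation statistics for methylation risk indices.

Implements the rank-based AUC with a DeLong-type confidence interval, the
median-unbiased (mid-p) odds ratio for 2x2 tables conditional on the margins,
control-quartile odds-ratio tables, genomic-region enrichment of a CpG
selection against an array background, polygenic risk scores and the
MethyLight percentage-of-methylated-reference (PMR).

The mid-p odds ratio is the value of the conditional odds ratio psi at which
the mid-p tail probability of Fisher's noncentral hypergeometric distribution
of the exposed-case cell equals one half; confidence limits invert the mid-p
tails at alpha/2. Tail probabilities are computed by direct summation over the
support with log-scale weights, which is exact and stable for the table sizes
encountered here (cells up to a few hundred).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

REGION_CLASSES = ("Island", "Shore", "Shelf", "OpenSea")

__all__ = [
    "ContingencyTable2x2",
    "QuartileTable",
    "roc_auc_ci",
    "midp_odds_ratio",
    "quartile_odds_table",
    "region_enrichment",
    "compute_prs",
    "compute_pmr",
    "REGION_CLASSES",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (exposed-case a, exposed-control b, reference-case c, reference-control d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")


@dataclass
class QuartileTable:
    """Per-quartile counts and odds ratios versus the bottom quartile."""

    cutpoints: np.ndarray
    control_counts: np.ndarray
    case_counts: np.ndarray
    odds_ratios: list
    ci_low: list
    ci_high: list
    adjusted: pd.DataFrame | None = None
    notes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        lo = np.r_[-np.inf, self.cutpoints]
        hi = np.r_[self.cutpoints, np.inf]
        return pd.DataFrame(
            {
                "quartile": [f"Q{i + 1}" for i in range(4)],
                "interval_low": lo,
                "interval_high": hi,
                "controls": self.control_counts,
                "cases": self.case_counts,
                "odds_ratio": self.odds_ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


# ---------------------------------------------------------------------------
# AUC


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"labels must contain exactly two classes, got {uniq}")
    return (labels == uniq.max()).astype(int)


def roc_auc_ci(scores, labels, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Mann-Whitney AUC with a DeLong-type asymptotic 95% CI.

    AUC = U / (n_case * n_control) with ties counted one half.  The variance
    uses the structural components (per-case and per-control placement
    values); the CI is normal on the AUC scale, clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    cases = scores[y == 1]
    controls = scores[y == 0]
    m, n = len(cases), len(controls)
    # placement of each case among controls and vice versa
    diff = cases[:, None] - controls[None, :]
    wins = (diff > 0).astype(float) + 0.5 * (diff == 0)
    auc = wins.mean()
    v_case = wins.mean(axis=1)  # per-case placement values
    v_ctrl = wins.mean(axis=0)
    var = (np.var(v_case, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v_ctrl, ddof=1) / n if n > 1 else 0.0
    )
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(auc), (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


# ---------------------------------------------------------------------------
# mid-p odds ratio


def _conditional_log_pmf(table: ContingencyTable2x2, log_psi: float):
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    k = np.arange(lo, hi + 1)
    logw = (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - (c1 - k) + 1)
        + k * log_psi
    )
    return k, logw - logsumexp(logw)


def _midp_upper_tail(table: ContingencyTable2x2, log_psi: float) -> float:
    """P(K > a) + 0.5 P(K = a) under odds ratio exp(log_psi); increasing in psi."""
    k, logp = _conditional_log_pmf(table, log_psi)
    p = np.exp(logp)
    return float(p[k > table.a].sum() + 0.5 * p[k == table.a].sum())


_LOG_PSI_MAX = 60.0


def _invert_midp(table: ContingencyTable2x2, target: float) -> float:
    """Odds ratio psi at which the upper mid-p tail equals ``target``."""
    f = lambda lp: _midp_upper_tail(table, lp) - target
    if f(_LOG_PSI_MAX) < 0:  # even psi -> inf leaves too little upper mass
        return np.inf
    if f(-_LOG_PSI_MAX) > 0:
        return 0.0
    return float(np.exp(brentq(f, -_LOG_PSI_MAX, _LOG_PSI_MAX, xtol=1e-12, rtol=8.9e-16)))


def midp_odds_ratio(
    table: ContingencyTable2x2, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Median-unbiased odds ratio with exact mid-p confidence limits.

    Returns ``(estimate, (low, high))``.  With a cell at the boundary of the
    conditional support the point estimate or a limit may be 0 or ``inf``;
    both margins of each axis must be positive.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a + b, c + d, a + c, b + d) <= 0:
        raise ValueError("both margins of the 2x2 table must be positive")
    lo_sup, hi_sup = max(0, (a + c) - (c + d)), min(a + b, a + c)
    if lo_sup == hi_sup:
        raise ValueError("degenerate table: the conditional support is a single point")
    # at the support boundary the upper mid-p tail never crosses 1/2:
    # the median-unbiased estimate sits at the corresponding boundary
    if a == hi_sup:
        est = np.inf
    elif a == lo_sup:
        est = 0.0
    else:
        est = _invert_midp(table, 0.5)
    # the upper mid-p tail is increasing in psi: a small upper tail pins the
    # lower limit, a large one the upper limit
    low = _invert_midp(table, alpha / 2)
    high = _invert_midp(table, 1 - alpha / 2)
    return est, (low, high)


# ---------------------------------------------------------------------------
# quartile table


def quartile_cutpoints(reference_scores) -> np.ndarray:
    """25/50/75 percentiles (linear interpolation) of the control reference."""
    ref = np.asarray(reference_scores, dtype=float)
    if ref.size < 4 or np.ptp(ref) == 0:
        raise ValueError("reference scores must be non-degenerate with >= 4 values")
    return np.percentile(ref, [25, 50, 75])


def assign_quartile(scores, cutpoints) -> np.ndarray:
    """0-based quartile index; intervals closed on the right (boundary -> lower)."""
    return np.searchsorted(np.asarray(cutpoints), np.asarray(scores, dtype=float), side="left")


def quartile_odds_table(
    scores,
    labels,
    reference_scores,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> QuartileTable:
    """Quartile odds-ratio table with control-derived cutpoints.

    Cutpoints are the quartiles of ``reference_scores`` (a control
    distribution); unadjusted ORs versus the bottom quartile use the mid-p
    median-unbiased estimator.  When ``covariates`` are given, adjusted ORs
    come from a logistic regression of the label on quartile indicators plus
    covariates with Wald CIs; non-convergence is recorded in ``notes``.
    """
    scores = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    cuts = quartile_cutpoints(reference_scores)
    q = assign_quartile(scores, cuts)
    control_counts = np.array([(y[q == i] == 0).sum() for i in range(4)])
    case_counts = np.array([(y[q == i] == 1).sum() for i in range(4)])

    ors, lows, highs, notes = [1.0], [np.nan], [np.nan], []
    for i in range(1, 4):
        tab = ContingencyTable2x2(
            int(case_counts[i]), int(control_counts[i]), int(case_counts[0]), int(control_counts[0])
        )
        try:
            est, (lo, hi) = midp_odds_ratio(tab, alpha=alpha)
        except ValueError as exc:
            est, lo, hi = np.nan, np.nan, np.nan
            notes.append(f"Q{i + 1}: {exc}")
        ors.append(est)
        lows.append(lo)
        highs.append(hi)

    adjusted = None
    if covariates is not None:
        adjusted, adj_notes = _adjusted_quartile_ors(y, q, covariates, alpha)
        notes.extend(adj_notes)

    return QuartileTable(cuts, control_counts, case_counts, ors, lows, highs, adjusted, notes)


def _adjusted_quartile_ors(y, quartile, covariates, alpha):
    import statsmodels.api as sm

    X = pd.get_dummies(pd.Categorical(quartile, categories=range(4)), prefix="Q", dtype=float)
    X = X.drop(columns="Q_0")
    X = pd.concat([X.reset_index(drop=True), covariates.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X)
    notes = []
    try:
        fit = sm.Logit(np.asarray(y, dtype=float), np.asarray(X, dtype=float)).fit(disp=0)
        if not fit.mle_retvals.get("converged", True):
            notes.append("adjusted logistic regression failed to converge")
        z = norm.ppf(1 - alpha / 2)
        rows = []
        for j, col in enumerate(X.columns):
            if not str(col).startswith("Q_"):
                continue
            beta, se = fit.params[j], fit.bse[j]
            rows.append(
                {
                    "quartile": f"Q{int(str(col).split('_')[1]) + 1}",
                    "odds_ratio": float(np.exp(beta)),
                    "ci_low": float(np.exp(beta - z * se)),
                    "ci_high": float(np.exp(beta + z * se)),
                }
            )
        return pd.DataFrame(rows), notes
    except Exception as exc:  # singular fits, separation
        notes.append(f"adjusted logistic regression unavailable: {exc}")
        return None, notes


# ---------------------------------------------------------------------------
# region enrichment


def region_enrichment(
    selected_cpgs,
    annotation: pd.DataFrame,
    background=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region-class mid-p odds ratios for a CpG selection vs the array.

    ``annotation`` must carry columns ``cpg_id`` and ``region_class``;
    ``background`` defaults to all annotated CpGs.  For each class the 2x2
    table is (selected vs not) x (in class vs not).
    """
    ann = annotation.set_index("cpg_id")["region_class"]
    bg = pd.Index(background) if background is not None else ann.index
    sel = pd.Index(selected_cpgs)
    if not sel.isin(bg).all():
        raise ValueError("selected CpGs must be a subset of the background")
    cls = ann.reindex(bg)
    in_sel = bg.isin(sel)
    rows = []
    for region in REGION_CLASSES:
        in_cls = (cls == region).to_numpy()
        if not in_cls.any():
            continue  # class absent from background: skipped
        a = int((in_sel & in_cls).sum())
        b = int((in_sel & ~in_cls).sum())
        c = int((~in_sel & in_cls).sum())
        d = int((~in_sel & ~in_cls).sum())
        est, (lo, hi) = midp_odds_ratio(ContingencyTable2x2(a, b, c, d), alpha=alpha)
        rows.append(
            {"region_class": region, "selected_in_class": a, "odds_ratio": est, "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PRS and PMR


def compute_prs(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    effect_allele_freqs: pd.Series | None = None,
) -> pd.Series:
    """Polygenic risk score: per-sample weighted sum of effect-allele dosages.

    ``dosages`` is sample x SNP with values in [0, 2]; ``weights`` has columns
    ``snp_id`` and ``beta`` (log odds ratios).  Missing dosages are imputed at
    twice the effect-allele frequency when frequencies are supplied, otherwise
    missingness is an error.
    """
    w = weights.set_index("snp_id")["beta"].astype(float)
    missing = [s for s in dosages.columns if s not in w.index]
    if missing:
        raise ValueError(f"no weights for SNPs: {missing}")
    X = dosages.astype(float).copy()
    if X.isna().any().any():
        if effect_allele_freqs is None:
            raise ValueError("missing dosages and no effect-allele frequencies for imputation")
        X = X.fillna(2.0 * effect_allele_freqs.reindex(X.columns))
    return X.mul(w.reindex(X.columns), axis=1).sum(axis=1).rename("prs")


def compute_pmr(sample_ratio: float, sssi_ratio: float) -> float:
    """Percentage of methylated reference: 100 * sample ratio / fully-methylated ratio."""
    if sssi_ratio <= 0:
        raise ValueError("the fully-methylated control ratio must be positive")
    return 100.0 * sample_ratio / sssi_ratio
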