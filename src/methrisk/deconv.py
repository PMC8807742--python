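"""Reference-based cell-type deconvolution of methylation beta values.

A marker panel is built from pure cell-type samples by one-vs-rest Wilcoxon
rank-sum tests (BH-FDR adjusted) combined with a mean-difference threshold;
per-sample fractions then solve a non-negative least-squares fit of the
sample's marker betas on the panel centroids, renormalised to sum to one.
The tumour-DNA fraction is additionally corrected by regressing it on the
epithelial fraction in controls with a local-polynomial (loess) smooth and
taking residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ReferencePanel",
    "PanelConstructionError",
    "InsufficientMarkersError",
    "build_reference_panel",
    "estimate_fractions",
    "correct_tumour_fraction",
    "CellTypeDeconvolver",
]


class PanelConstructionError(RuntimeError):
    """A cell type yielded no markers under the given thresholds."""


class InsufficientMarkersError(RuntimeError):
    """Too few panel markers present in the matrix to deconvolve."""


@dataclass
class ReferencePanel:
    """Marker CpGs with per-cell-type centroid betas.

    ``markers`` has one row per marker (cpg_id, cell_type, delta, p_adj);
    ``centroid`` is marker x cell-type mean betas over the pure samples.
    """

    markers: pd.DataFrame
    centroid: pd.DataFrame
    thresholds: dict

    @property
    def marker_cpgs(self) -> pd.Index:
        return self.centroid.index

    @property
    def cell_types(self) -> list:
        return list(self.centroid.columns)

    def counts_per_type(self) -> pd.Series:
        return self.markers["cell_type"].value_counts()


def build_reference_panel(
    pure_beta: pd.DataFrame,
    labels: pd.Series,
    p_adj_max: float = 0.01,
    delta_min: float | dict = 0.5,
    target_count_per_type: int | None = None,
) -> ReferencePanel:
    """Select type-exclusive marker CpGs from labelled pure-cell-type samples.

    For each cell type, every CpG is tested one-vs-rest with a two-sided
    Wilcoxon rank-sum test; p-values are Benjamini-Hochberg adjusted across
    CpGs.  Markers must satisfy ``p_adj < p_adj_max`` and an absolute group
    mean difference above ``delta_min`` (a single value or per-type map).
    When ``target_count_per_type`` is given, the delta threshold is instead
    auto-tuned per type to the smallest value yielding at most that many
    markers.  A CpG eligible for several types is attributed to the type
    with the largest absolute difference.
    """
    labels = labels.reindex(pure_beta.columns)
    types = sorted(labels.dropna().unique())
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("need at least 2 pure samples per cell type")

    X = pure_beta.to_numpy()
    rows = []
    for t in types:
        dmin = delta_min[t] if isinstance(delta_min, dict) else delta_min
        in_t = (labels == t).to_numpy()
        with np.errstate(all="ignore"):
            stat = mannwhitneyu(X[:, in_t], X[:, ~in_t], axis=1, alternative="two-sided")
        p_adj = multipletests(stat.pvalue, method="fdr_bh")[1]
        diff = X[:, in_t].mean(axis=1) - X[:, ~in_t].mean(axis=1)
        sig = p_adj < p_adj_max
        if target_count_per_type is not None:
            cand = np.abs(diff[sig])
            if len(cand) > target_count_per_type:
                dmin = np.sort(cand)[::-1][target_count_per_type]  # > dmin keeps <= target
        keep = sig & (np.abs(diff) > dmin)
        df = pd.DataFrame(
            {
                "cpg_id": pure_beta.index[keep],
                "cell_type": t,
                "delta": diff[keep],
                "p_adj": p_adj[keep],
                "delta_min_used": dmin,
            }
        )
        rows.append(df)
    markers = pd.concat(rows, ignore_index=True)
    # type-exclusive attribution: strongest |delta| wins
    markers = (
        markers.reindex(markers["delta"].abs().sort_values(ascending=False).index)
        .drop_duplicates("cpg_id")
        .sort_values(["cell_type", "cpg_id"])
        .reset_index(drop=True)
    )
    for t in types:
        if (markers["cell_type"] == t).sum() == 0:
            raise PanelConstructionError(f"no markers selected for cell type '{t}'")

    sel = pure_beta.loc[markers["cpg_id"].to_numpy()]
    centroid = pd.DataFrame(
        {t: sel.loc[:, (labels == t).to_numpy()].mean(axis=1) for t in types}
    )
    centroid.index.name = "cpg_id"
    thresholds = {
        "p_adj_max": p_adj_max,
        "delta_min": {t: float(markers.loc[markers.cell_type == t, "delta_min_used"].iloc[0]) for t in types},
        "target_count_per_type": target_count_per_type,
    }
    return ReferencePanel(markers.drop(columns="delta_min_used"), centroid, thresholds)


def estimate_fractions(beta: pd.DataFrame, panel: ReferencePanel) -> pd.DataFrame:
    """Per-sample cell fractions by constrained least squares on the panel.

    Solves non-negative least squares of each sample's marker betas on the
    centroid columns and renormalises to sum to one (missing markers are
    dropped).  Requires at least half the panel markers to be present.
    Returns a DataFrame indexed by sample id with one column per cell type,
    a ``tumour`` column (0 when the panel lacks a tumour class) and ``ic``
    aliasing the immune fraction.
    """
    present = panel.marker_cpgs.intersection(beta.index)
    if len(present) < 0.5 * len(panel.marker_cpgs):
        raise InsufficientMarkersError(
            f"only {len(present)}/{len(panel.marker_cpgs)} panel markers present"
        )
    C = panel.centroid.loc[present].to_numpy()
    Y = beta.loc[present].to_numpy()
    out = np.zeros((beta.shape[1], C.shape[1]))
    for j in range(Y.shape[1]):
        w, _ = nnls(C, Y[:, j])
        s = w.sum()
        out[j] = w / s if s > 0 else np.full(C.shape[1], 1.0 / C.shape[1])
    frac = pd.DataFrame(out, index=beta.columns.rename("sample_id"), columns=panel.cell_types)
    for col in ("epithelial", "fibroblast", "immune", "tumour"):
        if col not in frac.columns:
            frac[col] = 0.0
    frac["ic"] = frac["immune"]
    return frac[["epithelial", "fibroblast", "immune", "tumour", "ic"]]


def correct_tumour_fraction(
    fractions: pd.DataFrame,
    control_ids,
    span: float = 0.75,
) -> pd.DataFrame:
    """Residual-correct the tumour fraction against the epithelial fraction.

    A loess smooth of tumour on epithelial is fitted on controls only; every
    sample's ``tumour_corrected`` is its raw tumour fraction minus the smooth
    evaluated at its epithelial fraction (so it may be slightly negative).
    Samples outside the controls' epithelial range are extrapolated linearly
    from the end segments of the smooth and flagged.
    """
    control_ids = pd.Index(control_ids)
    ctrl = fractions.loc[control_ids]
    if len(ctrl) < 20:
        raise ValueError(f"need >= 20 controls for the loess fit, got {len(ctrl)}")
    fitted = lowess(ctrl["tumour"].to_numpy(), ctrl["epithelial"].to_numpy(),
                    frac=span, return_sorted=True)
    xf, yf = fitted[:, 0], fitted[:, 1]
    xf, idx = np.unique(xf, return_index=True)
    yf = yf[idx]
    x = fractions["epithelial"].to_numpy()
    pred = np.interp(x, xf, yf)
    below, above = x < xf[0], x > xf[-1]
    if len(xf) > 1:
        lo_slope = (yf[1] - yf[0]) / (xf[1] - xf[0])
        hi_slope = (yf[-1] - yf[-2]) / (xf[-1] - xf[-2])
        pred[below] = yf[0] + lo_slope * (x[below] - xf[0])
        pred[above] = yf[-1] + hi_slope * (x[above] - xf[-1])
    out = fractions.copy()
    out["tumour_corrected"] = out["tumour"].to_numpy() - pred
    out["tumour_corrected_extrapolated"] = below | above
    return out


class CellTypeDeconvolver(BaseEstimator, TransformerMixin):
    """Reference-based deconvolution as a scikit-learn transformer.

    ``fit`` builds the marker panel from pure cell-type samples (a CpG x
    sample beta DataFrame and per-sample type labels); ``transform`` maps a
    cohort beta matrix to per-sample cell fractions.

    Parameters
    ----------
    p_adj_max : float
        BH-adjusted rank-sum p-value ceiling for marker candidates.
    delta_min : float or dict
        Minimum absolute one-vs-rest mean beta difference, optionally per type.
    target_count_per_type : int, optional
        If set, auto-tune the delta threshold to keep at most this many
        markers per cell type.

    Attributes
    ----------
    panel_ : ReferencePanel
    """

    def __init__(self, p_adj_max: float = 0.01, delta_min=0.5, target_count_per_type=None):
        self.p_adj_max = p_adj_max
        self.delta_min = delta_min
        self.target_count_per_type = target_count_per_type

    def fit(self, X: pd.DataFrame, y):
        y = pd.Series(y, index=X.columns) if not isinstance(y, pd.Series) else y
        self.panel_ = build_reference_panel(
            X, y, p_adj_max=self.p_adj_max, delta_min=self.delta_min,
            target_count_per_type=self.target_count_per_type,
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "panel_"):
            raise RuntimeError("CellTypeDeconvolver is not fitted")
        return estimate_fractions(X, self.panel_)
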