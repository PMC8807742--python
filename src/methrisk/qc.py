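"""Beta-matrix quality control.

Detection-failure masking, sample/probe failure-rate filtering, k-nearest-
neighbour imputation of the surviving failures, probe-exclusion blocklists,
and the once-only discovery split.  The intensity-level sample filter used
upstream of beta matrices (median (un)methylated intensity cutoffs) needs raw
intensities and is therefore recorded in the report as not applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

logger = logging.getLogger(__name__)

__all__ = ["QcReport", "EmptyResultError", "qc_filter_impute", "exclude_probes", "split_discovery"]


class EmptyResultError(RuntimeError):
    """Raised when filtering removes every sample or probe."""


@dataclass
class QcReport:
    removed_samples: dict = field(default_factory=dict)  # id -> reason
    removed_probes: dict = field(default_factory=dict)
    imputed_count: int = 0
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "removed_samples": self.removed_samples,
            "removed_probes": self.removed_probes,
            "imputed_count": self.imputed_count,
            "notes": self.notes,
        }


def qc_filter_impute(
    beta: pd.DataFrame,
    detection_p: pd.DataFrame,
    p_thresh: float = 0.01,
    sample_fail_frac: float = 0.10,
    probe_fail_frac: float = 0.10,
    k: int = 10,
):
    """Mask failed probes, filter high-failure samples/probes, impute the rest.

    An entry with detection p-value above ``p_thresh`` is a failure.  Samples
    whose failure fraction exceeds ``sample_fail_frac`` are removed first,
    then probes exceeding ``probe_fail_frac``; the two filters are iterated
    to a fixed point so no retained row or column exceeds its threshold.
    Remaining failures are imputed from the ``k`` nearest probes (Euclidean
    distance over pairwise-complete samples, uniform weights).

    Returns ``(clean_beta, QcReport)``; the output contains no masked values.
    """
    if not 0 < p_thresh < 1:
        raise ValueError("p_thresh must lie in (0, 1)")
    if beta.shape != detection_p.shape or not beta.index.equals(detection_p.index) \
            or not beta.columns.equals(detection_p.columns):
        raise ValueError("beta and detection_p matrices must be conformable")

    report = QcReport()
    report.notes.append(
        "intensity-level sample filter (median methylated/unmethylated intensity) "
        "not applied: requires raw intensities"
    )
    failed = (detection_p > p_thresh) | beta.isna()
    probes = beta.index
    samples = beta.columns

    changed = True
    while changed:
        changed = False
        sub = failed.loc[probes, samples]
        bad_samples = samples[sub.mean(axis=0).to_numpy() > sample_fail_frac]
        if len(bad_samples):
            for s in bad_samples:
                report.removed_samples[s] = f"failure fraction > {sample_fail_frac}"
            samples = samples.difference(bad_samples, sort=False)
            changed = True
        if len(samples) == 0:
            raise EmptyResultError("all samples removed by the failure-rate filter")
        sub = failed.loc[probes, samples]
        bad_probes = probes[sub.mean(axis=1).to_numpy() > probe_fail_frac]
        if len(bad_probes):
            for p in bad_probes:
                report.removed_probes[p] = f"failure rate > {probe_fail_frac}"
            probes = probes.difference(bad_probes, sort=False)
            changed = True
        if len(probes) == 0:
            raise EmptyResultError("all probes removed by the failure-rate filter")

    out = beta.loc[probes, samples].copy()
    mask = failed.loc[probes, samples]
    report.imputed_count = int(mask.to_numpy().sum())
    if report.imputed_count:
        if k >= len(probes):
            raise ValueError(f"k={k} nearest probes requested but only {len(probes)} available")
        out = out.mask(mask)
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        # rows are probes, so each missing entry is filled from the k nearest
        # probes over their shared (non-missing) samples
        out = pd.DataFrame(imputer.fit_transform(out.to_numpy()), index=probes, columns=samples)
    return out, report


def exclude_probes(beta: pd.DataFrame, blocklists: dict) -> pd.DataFrame:
    """Drop all probes named in any blocklist; remaining order is preserved.

    ``blocklists`` maps a list name (e.g. non-CpG, SNP-related, trimodal) to
    a set of CpG ids.  Ids absent from the matrix are ignored and logged.
    """
    union: set = set()
    for name, ids in blocklists.items():
        ids = set(ids)
        missing = ids - set(beta.index)
        if missing:
            logger.info("blocklist %s: %d ids not on the array", name, len(missing))
        union |= ids
    out = beta.loc[~beta.index.isin(union)]
    if out.shape[0] == 0:
        warnings.warn("probe exclusion removed every probe", stacklevel=2)
    return out


def split_discovery(
    sheet: pd.DataFrame,
    train_frac: float = 2 / 3,
    seed: int = 0,
    stratify_by: str | None = None,
):
    """Random one-off split of the discovery cohort into train and validation.

    Returns ``(train_ids, validation_ids)`` — a disjoint, exhaustive
    partition.  With ``stratify_by`` (e.g. the case/control column) each
    stratum is split at ``train_frac`` so class proportions are preserved to
    within one sample.  The split is meant to be performed once and persisted.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    ids = sheet["sample_id"].to_numpy()
    if len(ids) < 3:
        raise ValueError("need at least 3 samples to split")
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        perm = rng.permutation(ids)
        n_train = int(round(train_frac * len(ids)))
        return list(perm[:n_train]), list(perm[n_train:])
    train, val = [], []
    for _, grp in sheet.groupby(stratify_by, sort=True):
        perm = rng.permutation(grp["sample_id"].to_numpy())
        n_train = int(round(train_frac * len(perm)))
        train += list(perm[:n_train])
        val += list(perm[n_train:])
    return train, val
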