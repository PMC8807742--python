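"""Evaluation statistics: AUC, mid-p odds ratios, quartiles, enrichment, PRS, PMR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methrisk.stats import (
    ContingencyTable2x2,
    compute_pmr,
    compute_prs,
    midp_odds_ratio,
    quartile_cutpoints,
    quartile_odds_table,
    region_enrichment,
    roc_auc_ci,
)
from methrisk.stats import _midp_upper_tail


def _pairwise_auc(scores, labels):
    scores, labels = np.asarray(scores, dtype=float), np.asarray(labels)
    cases, controls = scores[labels == 1], scores[labels == 0]
    wins = sum(1.0 if c > k else 0.5 if c == k else 0.0 for c in cases for k in controls)
    return wins / (len(cases) * len(controls))


def test_auc_enumeration_example():
    auc, _ = roc_auc_ci([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
    assert auc == pytest.approx(0.75)


def test_auc_perfect_separation():
    auc, (lo, hi) = roc_auc_ci([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert auc == 1.0 and hi == 1.0


def test_auc_null_permutation():
    rng = np.random.default_rng(1)
    scores = rng.normal(size=2000)
    labels = rng.permutation([0, 1] * 1000)
    auc, _ = roc_auc_ci(scores, labels)
    assert 0.47 <= auc <= 0.53


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(2, 25), st.integers(2, 25), st.integers(0, 10_000))
def test_auc_matches_exhaustive_pairwise_oracle(n1, n0, seed):
    rng = np.random.default_rng(seed)
    scores = np.round(rng.normal(size=n1 + n0), 1)  # rounding forces ties
    labels = np.r_[np.ones(n1), np.zeros(n0)].astype(int)
    auc, _ = roc_auc_ci(scores, labels)
    assert auc == pytest.approx(_pairwise_auc(scores, labels), abs=1e-12)


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        roc_auc_ci([1, 2, 3], [1, 1, 1])


# ---------------------------------------------------------------------------


def test_midp_symmetric_table_is_one():
    est, (lo, hi) = midp_odds_ratio(ContingencyTable2x2(20, 20, 20, 20))
    assert est == pytest.approx(1.0, abs=1e-9)
    assert lo < 1 < hi


def test_midp_tail_probability_at_estimate_is_half():
    for tab in [ContingencyTable2x2(57, 74, 3, 75), ContingencyTable2x2(13, 7, 5, 21),
                ContingencyTable2x2(3, 1, 1, 3)]:
        est, (lo, hi) = midp_odds_ratio(tab)
        assert _midp_upper_tail(tab, np.log(est)) == pytest.approx(0.5, abs=1e-6)
        assert _midp_upper_tail(tab, np.log(lo)) == pytest.approx(0.025, abs=1e-6)
        assert _midp_upper_tail(tab, np.log(hi)) == pytest.approx(0.975, abs=1e-6)


def test_midp_attenuated_relative_to_cross_product():
    tab = ContingencyTable2x2(57, 74, 3, 75)
    est, _ = midp_odds_ratio(tab)
    cross = (57 * 75) / (74 * 3)
    assert 1 < est < cross


def test_midp_large_balanced_counts_near_cross_product():
    tab = ContingencyTable2x2(300, 200, 200, 300)
    est, _ = midp_odds_ratio(tab)
    cross = (300 * 300) / (200 * 200)
    assert est == pytest.approx(cross, rel=0.02)


def test_midp_zero_margin_errors_and_zero_cell_boundary():
    with pytest.raises(ValueError, match="margins"):
        midp_odds_ratio(ContingencyTable2x2(0, 5, 0, 5))
    est, (lo, hi) = midp_odds_ratio(ContingencyTable2x2(10, 5, 0, 7))
    assert np.isinf(est) or est > 1  # boundary cell: upper tail may never reach 0.5
    assert np.isinf(hi)
    est0, (lo0, hi0) = midp_odds_ratio(ContingencyTable2x2(0, 5, 7, 7))
    assert est0 < 1 and lo0 == 0.0


def test_negative_or_fractional_counts_rejected():
    with pytest.raises(ValueError):
        ContingencyTable2x2(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        ContingencyTable2x2(1.5, 2, 3, 4)


# ---------------------------------------------------------------------------


def test_quartile_control_counts_297():
    """297 control-derived cutpoints give per-quartile control counts 75/74/74/74."""
    rng = np.random.default_rng(2)
    ref = rng.normal(size=297)
    scores = np.r_[ref, rng.normal(1.0, 1.0, 50)]
    labels = np.r_[np.zeros(297), np.ones(50)].astype(int)
    qt = quartile_odds_table(scores, labels, ref)
    assert qt.control_counts.tolist() == [75, 74, 74, 74]


def test_quartile_null_cis_cover_one():
    rng = np.random.default_rng(3)
    ref = rng.normal(size=400)
    scores = np.r_[ref, rng.normal(size=400)]
    labels = np.r_[np.zeros(400), np.ones(400)].astype(int)
    qt = quartile_odds_table(scores, labels, ref)
    for lo, hi in zip(qt.ci_low[1:], qt.ci_high[1:]):
        assert lo < 1 < hi


def test_quartile_adjusted_ors_present():
    rng = np.random.default_rng(4)
    ref = rng.normal(size=200)
    scores = np.r_[ref, rng.normal(0.8, 1, 200)]
    labels = np.r_[np.zeros(200), np.ones(200)].astype(int)
    cov = pd.DataFrame({"age": rng.uniform(30, 70, 400)})
    qt = quartile_odds_table(scores, labels, ref, covariates=cov)
    assert qt.adjusted is not None and len(qt.adjusted) == 3
    assert (qt.adjusted["odds_ratio"] > 0).all()


def test_quartile_degenerate_reference_errors():
    with pytest.raises(ValueError):
        quartile_cutpoints(np.full(100, 1.0))


# ---------------------------------------------------------------------------


def _annotation(n, rng):
    return pd.DataFrame(
        {
            "cpg_id": [f"cg{i:05d}" for i in range(n)],
            "region_class": rng.choice(
                ["Island", "Shore", "Shelf", "OpenSea"], n, p=[0.2, 0.25, 0.1, 0.45]
            ),
        }
    )


def test_region_enrichment_null_covers_one():
    rng = np.random.default_rng(5)
    ann = _annotation(20_000, rng)
    selected = rng.choice(ann["cpg_id"], size=2000, replace=False)
    res = region_enrichment(selected, ann)
    assert len(res) == 4
    assert ((res["ci_low"] < 1) & (res["ci_high"] > 1)).all()


def test_region_enrichment_extreme_composition():
    rng = np.random.default_rng(6)
    ann = _annotation(2000, rng)
    opensea = ann.loc[ann["region_class"] == "OpenSea", "cpg_id"]
    res = region_enrichment(opensea, ann).set_index("region_class")
    assert np.isinf(res.loc["OpenSea", "odds_ratio"])
    assert res.loc["Island", "odds_ratio"] == 0.0


def test_region_enrichment_hand_table_direction():
    ann = pd.DataFrame(
        {"cpg_id": [f"c{i}" for i in range(8)], "region_class": ["Island"] * 4 + ["OpenSea"] * 4}
    )
    res = region_enrichment(["c4", "c5", "c6", "c0"], ann).set_index("region_class")
    est = res.loc["OpenSea", "odds_ratio"]
    assert 1 < est < 9.0  # attenuated versus the cross-product of the (3,1;1,3) table


def test_region_enrichment_requires_subset():
    ann = _annotation(100, np.random.default_rng(7))
    with pytest.raises(ValueError, match="subset"):
        region_enrichment(["nope"], ann)


# ---------------------------------------------------------------------------


def test_prs_hand_arithmetic_and_linearity():
    dos = pd.DataFrame({"rs1": [2.0, 0.0], "rs2": [1.0, 0.0]}, index=["a", "b"])
    w = pd.DataFrame({"snp_id": ["rs1", "rs2"], "beta": [0.1, -0.2]})
    prs = compute_prs(dos, w)
    assert prs["a"] == pytest.approx(0.0)
    assert prs["b"] == pytest.approx(0.0)
    w2 = w.assign(beta=w["beta"] * 2)
    dos2 = pd.DataFrame({"rs1": [2.0, 1.0], "rs2": [0.0, 2.0]}, index=["a", "b"])
    np.testing.assert_allclose(compute_prs(dos2, w2), 2 * compute_prs(dos2, w))


def test_prs_missing_handling():
    dos = pd.DataFrame({"rs1": [np.nan, 2.0]}, index=["a", "b"])
    w = pd.DataFrame({"snp_id": ["rs1"], "beta": [0.5]})
    with pytest.raises(ValueError, match="frequencies"):
        compute_prs(dos, w)
    prs = compute_prs(dos, w, effect_allele_freqs=pd.Series({"rs1": 0.25}))
    assert prs["a"] == pytest.approx(0.5 * 0.5)
    with pytest.raises(ValueError, match="no weights"):
        compute_prs(pd.DataFrame({"rsX": [1.0]}), w)


def test_pmr():
    assert compute_pmr(0.08, 0.08) == 100.0
    assert compute_pmr(0.0, 0.08) == 0.0
    assert compute_pmr(0.02, 0.08) == 25.0
    with pytest.raises(ValueError):
        compute_pmr(0.02, 0.0)
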