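"""Polygenic score: allele alignment, scoring, QC, standardization, calibration."""

import numpy as np
import pandas as pd
import pytest

import staturepgs as sp
from staturepgs.errors import AlignmentError, ValidationError
from staturepgs.pgs import (
    DosageMatrix,
    QCThresholds,
    WeightTable,
    align_and_filter,
    compute_pgs,
    fit_calibration,
    predict_height_sds,
    sample_qc,
    standardize_pgs,
)


def make_weights(rows):
    return WeightTable(
        pd.DataFrame(rows, columns=["id", "effect_allele", "other_allele", "weight", "imputation_r2"])
    )


def make_dosages(values: dict, alleles: dict) -> DosageMatrix:
    dos = pd.DataFrame(values, index=pd.Index([f"s{i}" for i in range(len(next(iter(values.values()))))], name="sample_id"))
    al = pd.DataFrame(
        {"coded": {k: v[0] for k, v in alleles.items()}, "other": {k: v[1] for k, v in alleles.items()}}
    )
    al.index.name = "id"
    return DosageMatrix(dos, al)


@pytest.fixture
def basic_weights():
    return make_weights(
        [
            ("v1", "A", "G", 0.3, 0.99),   # identity orientation
            ("v2", "C", "T", -0.2, 0.95),  # coded on the other allele -> flip
            ("v3", "A", "T", 0.5, 0.99),   # strand-ambiguous -> dropped
            ("v4", "G", "C", 0.5, 0.99),   # strand-ambiguous -> dropped
            ("v5", "T", "C", 0.1, 0.65),   # below the imputation R^2 threshold
            ("v6", "A", "C", 0.4, 0.99),   # allele pair matches neither orientation
        ]
    )


@pytest.fixture
def basic_dosages():
    return make_dosages(
        {
            "v1": [1.2, 0.0], "v2": [0.5, 2.0], "v3": [1.0, 1.0],
            "v4": [1.0, 1.0], "v5": [2.0, 0.0], "v6": [1.0, 1.0],
        },
        {"v1": ("A", "G"), "v2": ("T", "C"), "v3": ("A", "T"),
         "v4": ("G", "C"), "v5": ("T", "C"), "v6": ("G", "T")},
    )


def test_alignment_orientations_and_filters(basic_weights, basic_dosages):
    with pytest.warns(UserWarning, match="neither allele orientation"):
        aligned, report = align_and_filter(basic_weights, basic_dosages, 0.7)
    assert report == {
        "matched": 2, "flipped": 1, "dropped_ambiguous": 2,
        "dropped_low_r2": 1, "dropped_unmatched": 1, "absent_from_dosages": 0,
    }
    # identity orientation preserved; other-allele coding flipped to 2 - d
    assert aligned.dosages.loc["s0", "v1"] == pytest.approx(1.2)
    assert aligned.dosages.loc["s0", "v2"] == pytest.approx(1.5)
    assert set(aligned.variant_ids) == {"v1", "v2"}
    assert (aligned.alleles["coded"] == ["A", "C"]).all()


def test_alignment_zero_overlap_is_hard_error(basic_weights):
    other = make_dosages({"x9": [1.0]}, {"x9": ("A", "G")})
    with pytest.raises(AlignmentError):
        align_and_filter(basic_weights, other)


def test_compute_pgs_hand_sum(basic_weights, basic_dosages):
    with pytest.warns(UserWarning):
        aligned, _ = align_and_filter(basic_weights, basic_dosages, 0.7)
    scores = compute_pgs(basic_weights, aligned)
    # s0: 0.3*1.2 + (-0.2)*1.5 = 0.06 ; s1: 0.3*0 + (-0.2)*0 = 0
    assert scores["s0"] == pytest.approx(0.06)
    assert scores["s1"] == pytest.approx(0.0)


def test_compute_pgs_examples():
    w = make_weights([("a", "A", "G", 0.3, 1.0), ("b", "C", "T", -0.2, 1.0)])
    d = make_dosages({"a": [1.5, 1.5], "b": [1.5, 1.5]}, {"a": ("A", "G"), "b": ("C", "T")})
    scores = compute_pgs(w, d)
    assert np.allclose(scores, 0.45 - 0.30)
    w0 = make_weights([("a", "A", "G", 0.0, 1.0), ("b", "C", "T", 0.0, 1.0)])
    assert np.allclose(compute_pgs(w0, d), 0.0)
    w1 = make_weights([("a", "A", "G", 0.5, 1.0)])
    d1 = make_dosages({"a": [2.0]}, {"a": ("A", "G")})
    assert compute_pgs(w1, d1)["s0"] == pytest.approx(1.0)


def test_compute_pgs_mean_imputes_missing():
    w = make_weights([("a", "A", "G", 1.0, 1.0)])
    d = make_dosages({"a": [0.0, 2.0, np.nan]}, {"a": ("A", "G")})
    scores = compute_pgs(w, d)
    assert scores["s2"] == pytest.approx(1.0)  # cohort mean dosage of the called samples
    d_all_nan = make_dosages({"a": [np.nan, np.nan]}, {"a": ("A", "G")})
    with pytest.warns(UserWarning, match="no called dosages"):
        scores = compute_pgs(w, d_all_nan)
    assert np.allclose(scores, 0.0)


def test_pgs_linearity():
    rng = np.random.default_rng(5)
    ids = [f"v{i}" for i in range(20)]
    dos = pd.DataFrame(rng.uniform(0, 2, (10, 20)), columns=ids,
                       index=pd.Index([f"s{i}" for i in range(10)], name="sample_id"))
    al = pd.DataFrame({"coded": ["A"] * 20, "other": ["G"] * 20}, index=pd.Index(ids, name="id"))
    d = DosageMatrix(dos, al)
    wvals = rng.normal(0, 1, 20)
    w1 = WeightTable(pd.DataFrame({"id": ids, "effect_allele": "A", "other_allele": "G", "weight": wvals}))
    w2 = WeightTable(pd.DataFrame({"id": ids, "effect_allele": "A", "other_allele": "G", "weight": 2 * wvals}))
    np.testing.assert_allclose(compute_pgs(w2, d), 2 * compute_pgs(w1, d), rtol=1e-12)


def test_allele_flip_leaves_score_differences_invariant():
    """Recoding a variant to the opposite allele shifts all scores by the same
    constant, so between-sample score differences are unchanged."""
    rng = np.random.default_rng(6)
    ids = ["v0", "v1", "v2"]
    w = make_weights([("v0", "A", "G", 0.4, 1.0), ("v1", "C", "T", -0.3, 1.0), ("v2", "G", "T", 0.2, 1.0)])
    vals = rng.uniform(0, 2, (6, 3))
    d_eff = make_dosages({i: vals[:, k] for k, i in enumerate(ids)},
                         {"v0": ("A", "G"), "v1": ("C", "T"), "v2": ("G", "T")})
    # same data with v1 coded on its other allele
    flipped_vals = dict(d_eff.dosages)
    d_flip = make_dosages(
        {"v0": vals[:, 0], "v1": 2 - vals[:, 1], "v2": vals[:, 2]},
        {"v0": ("A", "G"), "v1": ("T", "C"), "v2": ("G", "T")},
    )
    s1 = compute_pgs(w, align_and_filter(w, d_eff)[0])
    s2 = compute_pgs(w, align_and_filter(w, d_flip)[0])
    np.testing.assert_allclose(s1, s2, atol=1e-12)  # alignment recodes to effect allele


def test_sample_qc_cascade():
    n, m = 42, 100
    rng = np.random.default_rng(0)
    ids = [f"v{i}" for i in range(m)]
    mat = rng.binomial(2, 0.5, (n, m)).astype(float)
    mat[40, :3] = np.nan           # 3% missing -> removed
    mat[41, :] = 1.0               # all-het outlier, far beyond 4 SD -> removed
    dos = DosageMatrix(
        pd.DataFrame(mat, columns=ids, index=pd.Index([f"s{i}" for i in range(n)], name="sample_id")),
        pd.DataFrame({"coded": ["A"] * m, "other": ["G"] * m}, index=pd.Index(ids, name="id")),
    )
    kept, ledger = sample_qc(dos, [("s0", "s1", 0.5)], QCThresholds(), rng=1)
    assert len(ledger["kinship"]) == 1 and ledger["kinship"][0] in ("s0", "s1")
    assert ledger["missingness"] == ["s40"]
    assert ledger["heterozygosity"] == ["s41"]
    assert len(kept) == n - 3

    kept_all, ledger_all = sample_qc(dos, [("s0", "s1", 0.1)], QCThresholds(missingness_max=0.5, het_sd_max=50), rng=1)
    assert len(kept_all) == n and not any(ledger_all.values())


def test_standardize_pgs():
    ref = np.array([8.0, 10.0, 12.0])
    res = standardize_pgs(pd.Series([10.0, 7.0]), ref)
    assert res.sds.iloc[0] == pytest.approx(0.0)
    assert res.sds.iloc[1] == pytest.approx(-1.5)
    self_std = standardize_pgs(pd.Series(ref), ref)
    assert self_std.sds.mean() == pytest.approx(0.0, abs=1e-12)
    assert self_std.sds.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValidationError):
        standardize_pgs(pd.Series([1.0]), np.array([5.0, 5.0]))


def test_calibration_perfect_fit_and_default_pcs():
    pgs = np.linspace(-2, 2, 30)
    model = fit_calibration(0.6 * pgs, pgs)
    assert model.slope == pytest.approx(0.6, abs=1e-10)
    assert model.intercept == pytest.approx(0.0, abs=1e-10)
    assert predict_height_sds(model, 0.0) == pytest.approx(model.intercept)
    np.testing.assert_allclose(predict_height_sds(model, pgs), 0.6 * pgs, atol=1e-10)


def test_calibration_recovery_moderate_n():
    rng = np.random.default_rng(42)
    n = 2000
    pgs = rng.normal(0, 1, n)
    height = 0.62 * pgs + rng.normal(0, 0.79, n)
    model = fit_calibration(height, pgs)
    assert model.slope == pytest.approx(0.62, abs=0.06)


def test_calibration_rank_deficient_names_column():
    pgs = np.linspace(-1, 1, 20)
    pcs = pd.DataFrame({"pc1": pgs})  # collinear with the score
    with pytest.raises(ValidationError, match="collinear"):
        fit_calibration(0.5 * pgs, pgs, pcs=pcs)
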