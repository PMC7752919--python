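"""Reference standardization: quantile mapping, IPW weights, robust scaling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import median_abs_deviation

from metacohort.integrate import (
    compute_ipw_weights,
    fit_affiliation_model,
    merge_cohorts,
    prepare_rnaseq,
    quantile_normalize_to_reference,
    standardize_to_reference,
    truncate_to_reference,
    weighted_mad,
    weighted_median,
)


# --------------------------------------------------------------- robust stats
def oracle_weighted_median(x, w):
    """Independent enumeration of the cumulative-weight definition."""
    pairs = sorted(zip(x, w))
    total = sum(w for _, w in pairs)
    cum = 0.0
    for i, (xi, wi) in enumerate(pairs):
        cum += wi
        if cum > total / 2:
            return xi
        if cum == total / 2:
            return 0.5 * (xi + pairs[i + 1][0])
    return pairs[-1][0]


def test_weighted_median_toy_matches_enumeration():
    x = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.0]
    w = [1, 1, 1, 5, 1, 1, 1]
    assert weighted_median(x, w) == oracle_weighted_median(x, w)


@pytest.mark.parametrize("seed", range(6))
def test_weighted_median_random_cases_match_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(2, 12)
    x = rng.normal(size=n)
    w = rng.integers(1, 6, size=n).astype(float)
    assert weighted_median(x, w) == pytest.approx(oracle_weighted_median(x, w))


def test_weighted_median_exact_half_uses_midpoint():
    assert weighted_median([1.0, 3.0], [1.0, 1.0]) == 2.0


def test_unit_weight_mad_matches_raw_mad():
    rng = np.random.default_rng(1)
    x = rng.normal(size=31)
    assert weighted_mad(x, np.ones_like(x)) == pytest.approx(
        median_abs_deviation(x, scale=1.0)
    )


# ------------------------------------------------------ quantile normalization
def test_prepare_rnaseq_all_zero_matrix():
    mat = pd.DataFrame(np.zeros((4, 3)), index=list("abcd"), columns=list("xyz"))
    out = prepare_rnaseq(mat, offset=1.0)
    np.testing.assert_array_equal(out.to_numpy(), np.zeros((4, 3)))


def test_prepare_rnaseq_identical_columns_unchanged():
    col = np.array([0.0, 3.0, 7.0, 15.0])
    mat = pd.DataFrame(np.column_stack([col] * 3), index=list("abcd"),
                       columns=list("xyz"))
    out = prepare_rnaseq(mat)
    np.testing.assert_allclose(out.to_numpy(), np.log2(mat.to_numpy() + 1))


def test_prepare_rnaseq_three_by_three_rank_average_oracle():
    # hand computation: log2(x+1), sort each column, average across columns
    # at each rank, map back by rank
    mat = pd.DataFrame(
        [[0.0, 3.0, 1.0], [3.0, 0.0, 7.0], [7.0, 7.0, 0.0]],
        index=list("abc"), columns=list("xyz"),
    )
    logged = np.log2(mat.to_numpy() + 1)  # ranks per column: a<b<c, b<a<c, c<a<b
    target = np.sort(logged, axis=0).mean(axis=1)
    expected = np.empty_like(logged)
    for j in range(3):
        order = np.argsort(logged[:, j])
        expected[order, j] = target
    np.testing.assert_allclose(prepare_rnaseq(mat).to_numpy(), expected)


def test_prepare_rnaseq_rejects_negative():
    with pytest.raises(ValueError, match="non-negative"):
        prepare_rnaseq(pd.DataFrame([[-1.0]]))


def test_qn_permutation_of_reference_unchanged():
    ref = np.array([1.0, 2.0, 5.0, 9.0])
    mat = pd.DataFrame({"s1": [5.0, 1.0, 9.0, 2.0]}, index=list("abcd"))
    out = quantile_normalize_to_reference(mat, ref)
    np.testing.assert_array_equal(out["s1"].to_numpy(), [5.0, 1.0, 9.0, 2.0])


def test_qn_constant_reference_collapses_all_values():
    mat = pd.DataFrame({"s1": [5.0, 1.0, 9.0]}, index=list("abc"))
    out = quantile_normalize_to_reference(mat, np.array([4.0, 4.0, 4.0]))
    np.testing.assert_array_equal(out["s1"].to_numpy(), [4.0, 4.0, 4.0])


def test_qn_sorted_columns_equal_reference_exactly():
    rng = np.random.default_rng(3)
    ref = np.sort(rng.normal(size=50))
    mat = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("wxyz"))
    out = quantile_normalize_to_reference(mat, ref)
    for c in out.columns:
        np.testing.assert_array_equal(np.sort(out[c].to_numpy()), ref)


def test_qn_ties_mapped_to_span_mean():
    ref = np.array([10.0, 20.0, 30.0, 40.0])
    mat = pd.DataFrame({"s1": [1.0, 1.0, 2.0, 3.0]}, index=list("abcd"))
    out = quantile_normalize_to_reference(mat, ref)
    np.testing.assert_array_equal(out["s1"].to_numpy(), [15.0, 15.0, 30.0, 40.0])


def test_qn_interpolation_matches_hand_oracle():
    # 5-point reference quantiles [0,2,6,8,10] sit at grid fractions
    # 0, .25, .5, .75, 1; interpolating 3 features at fractions 0, .5, 1
    # gives [0, 6, 10], assigned by rank
    ref = np.array([0.0, 2.0, 6.0, 8.0, 10.0])
    mat = pd.DataFrame({"s1": [7.0, 1.0, 4.0]}, index=list("abc"))
    out = quantile_normalize_to_reference(mat, ref, interpolate=True)
    np.testing.assert_allclose(out["s1"].to_numpy(), [10.0, 0.0, 6.0])


def test_qn_nonfinite_reference_rejected():
    with pytest.raises(ValueError, match="finite"):
        quantile_normalize_to_reference(
            pd.DataFrame({"s1": [1.0, 2.0]}), np.array([1.0, np.nan])
        )


def test_qn_length_mismatch_without_interpolation_errors():
    with pytest.raises(ValueError, match="interpolate"):
        quantile_normalize_to_reference(
            pd.DataFrame({"s1": [1.0, 2.0, 3.0]}), np.array([1.0, 2.0])
        )


# --------------------------------------------------------- affiliation + IPW
def _clin_binary(n, p, seed, extra_balanced=True):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "gender": np.where(rng.random(n) < p, "M", "F"),
            "age": rng.normal(65, 10, n),
            "site": np.where(rng.random(n) < 0.5, "colon", "rectum"),
            "msi": np.where(rng.random(n) < 0.15, "MSI", "MSS"),
            "stage": rng.choice(["I", "II", "III", "IV"], n),
        },
        index=pd.RangeIndex(n).map(lambda i: f"n{seed}_{i}"),
    )


def test_intercept_only_model_gives_half_probabilities():
    clin_d = _clin_binary(50, 0.5, 1)
    clin_r = _clin_binary(50, 0.5, 2)
    model = fit_affiliation_model(clin_d, clin_r, candidates=())
    probs = model.predict_proba(clin_d)
    np.testing.assert_allclose(probs, 0.5, atol=1e-8)
    w = compute_ipw_weights(model, clin_d)
    np.testing.assert_allclose(w.to_numpy(), 1.0, atol=1e-8)
    assert model.selected_covariates_ == []


def test_strong_covariate_is_selected_and_aic_matches_direct_fit():
    import statsmodels.api as sm

    clin_d = _clin_binary(500, 0.9, 3)
    clin_r = _clin_binary(500, 0.1, 4)
    model = fit_affiliation_model(clin_d, clin_r, candidates=("gender", "age"))
    assert "gender" in model.selected_covariates_

    # independent AIC computation for the two one-covariate candidates
    pooled = pd.concat([clin_d, clin_r])
    y = np.r_[np.ones(500), np.zeros(500)]
    male = (pooled["gender"] == "M").astype(float).to_numpy()
    aic_gender = sm.Logit(y, sm.add_constant(male)).fit(disp=0).aic
    aic_age = sm.Logit(y, sm.add_constant(pooled["age"].to_numpy())).fit(disp=0).aic
    assert aic_gender < aic_age
    step1 = model.trace_[1]
    assert step1["added"] == "gender"
    assert step1["aic"] == pytest.approx(aic_gender, rel=1e-6)


def test_selection_trace_is_monotone_decreasing():
    clin_d = _clin_binary(300, 0.8, 5)
    clin_r = _clin_binary(300, 0.3, 6)
    model = fit_affiliation_model(clin_d, clin_r)
    aics = [t["aic"] for t in model.trace_]
    assert all(a2 < a1 for a1, a2 in zip(aics, aics[1:]))


def test_weights_truncated_at_five():
    # saturated single binary covariate: per-stratum Pd/(1-Pd) equals the
    # stratum count ratio nD/nR; 73 vs 10 -> raw 7.3 -> truncated to 5
    clin_d = pd.DataFrame(
        {"gender": ["M"] * 73 + ["F"] * 27}, index=[f"d{i}" for i in range(100)]
    )
    clin_r = pd.DataFrame(
        {"gender": ["M"] * 10 + ["F"] * 90, }, index=[f"r{i}" for i in range(100)]
    )
    model = fit_affiliation_model(clin_d, clin_r, candidates=("gender",))
    w = compute_ipw_weights(model, clin_d)
    males = clin_d["gender"] == "M"
    np.testing.assert_allclose(w[males].to_numpy(), 5.0, atol=1e-6)
    np.testing.assert_allclose(w[~males].to_numpy(), 27.0 / 90.0, rtol=1e-4)
    assert w.attrs["n_truncated"] == 73
    assert ((w > 0) & (w <= 5.0)).all()


def test_weight_direction_switch_inverts_ratio():
    clin_d = pd.DataFrame({"gender": ["M"] * 30 + ["F"] * 70},
                          index=[f"d{i}" for i in range(100)])
    clin_r = pd.DataFrame({"gender": ["M"] * 60 + ["F"] * 40},
                          index=[f"r{i}" for i in range(100)])
    model = fit_affiliation_model(clin_d, clin_r, candidates=("gender",))
    w_printed = compute_ipw_weights(model, clin_d, direction="pd_over_pr")
    w_conv = compute_ipw_weights(model, clin_d, direction="pr_over_pd")
    np.testing.assert_allclose(
        (w_printed * w_conv).to_numpy(), 1.0, rtol=1e-6
    )
    # conventional direction up-weights samples typical of the reference
    males = clin_d["gender"] == "M"
    assert w_conv[males].min() > w_conv[~males].max()


# ---------------------------------------------------------- standardization
def test_standardize_fixed_point_on_reference_itself():
    rng = np.random.default_rng(7)
    ref = pd.DataFrame(rng.normal(8, 2, (5, 21)),
                       index=[f"g{i}" for i in range(5)],
                       columns=[f"s{i}" for i in range(21)])
    out = standardize_to_reference(ref, np.ones(21), ref)
    np.testing.assert_allclose(out.to_numpy(), ref.to_numpy(), atol=1e-10)


def test_standardized_median_and_mad_equal_reference():
    rng = np.random.default_rng(8)
    ref = pd.DataFrame(rng.normal(0, 1, (4, 25)),
                       index=list("abcd"), columns=[f"r{i}" for i in range(25)])
    d = pd.DataFrame(rng.normal(5, 3, (4, 31)),
                     index=list("abcd"), columns=[f"d{i}" for i in range(31)])
    out = standardize_to_reference(d, np.ones(31), ref)
    for g in ref.index:
        assert np.median(out.loc[g]) == pytest.approx(np.median(ref.loc[g]))
        assert median_abs_deviation(out.loc[g], scale=1.0) == pytest.approx(
            median_abs_deviation(ref.loc[g], scale=1.0)
        )


def test_zero_scale_gene_gets_location_only_shift():
    ref = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g1"], columns=list("abc"))
    d = pd.DataFrame([[7.0, 7.0, 7.0]], index=["g1"], columns=list("xyz"))
    out = standardize_to_reference(d, np.ones(3), ref)
    np.testing.assert_array_equal(out.loc["g1"].to_numpy(), [2.0, 2.0, 2.0])


def test_truncate_clips_to_reference_range():
    ref = pd.DataFrame([[0.0, 10.0], [2.0, 4.0]], index=["g1", "g2"],
                       columns=["r1", "r2"])
    mat = pd.DataFrame([[-5.0, 3.0, 12.0], [1.0, 3.0, 9.0]],
                       index=["g1", "g2"], columns=list("xyz"))
    out = truncate_to_reference(mat, ref)
    np.testing.assert_array_equal(out.loc["g1"].to_numpy(), [0.0, 3.0, 10.0])
    np.testing.assert_array_equal(out.loc["g2"].to_numpy(), [2.0, 3.0, 4.0])


def test_truncate_missing_gene_errors():
    ref = pd.DataFrame([[0.0, 1.0]], index=["g1"], columns=["r1", "r2"])
    mat = pd.DataFrame([[0.5, 0.5]], index=["gX"], columns=["a", "b"])
    with pytest.raises(KeyError, match="gX"):
        truncate_to_reference(mat, ref)


# -------------------------------------------------------------------- merging
def _merge_inputs():
    rng = np.random.default_rng(9)
    m1 = pd.DataFrame(rng.normal(size=(3, 5)), index=["g1", "g2", "g3"],
                      columns=[f"a{i}" for i in range(5)])
    m2 = pd.DataFrame(rng.normal(size=(3, 5)), index=["g2", "g3", "g4"],
                      columns=[f"b{i}" for i in range(5)])
    clin = pd.DataFrame(
        {
            "dataset_id": ["D1"] * 5 + ["D2"] * 5,
            "stage": ["I", "II", "unknown", "III", "IV", "I", "I", "II", "unknown", "III"],
        },
        index=list(m1.columns) + list(m2.columns),
    )
    return m1, m2, clin


def test_merge_intersects_genes_and_drops_unknown_stage():
    m1, m2, clin = _merge_inputs()
    cohort = merge_cohorts({"D1": m1, "D2": m2}, clin, reference_id="D1")
    assert list(cohort.matrix.index) == ["g2", "g3"]
    assert cohort.matrix.shape[1] == 8  # 10 samples, 2 unknown stage
    assert {entry["dropped"] for entry in cohort.stage_log} == {1}
    assert cohort.reference_id == "D1"


def test_merge_duplicate_sample_ids_error():
    m1, m2, clin = _merge_inputs()
    m2 = m2.rename(columns={"b0": "a0"})
    with pytest.raises(ValueError, match="duplicate"):
        merge_cohorts({"D1": m1, "D2": m2}, clin, reference_id="D1")


def test_merge_requires_two_datasets():
    m1, _, clin = _merge_inputs()
    with pytest.raises(ValueError, match="two datasets"):
        merge_cohorts({"D1": m1}, clin, reference_id="D1")
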