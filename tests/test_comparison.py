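"""Cohort-level analysis: ratio summaries, categories, regression, correlation."""

import numpy as np
import pandas as pd
import pytest

from mammodose.comparison import (
    AGDComparison,
    density_categories,
    fit_glandularity_regression,
    ratio_covariate_correlation,
    summarize_ratios,
    thickness_class,
)


def _triples(rows):
    frame = pd.DataFrame(
        rows,
        columns=["thickness_mm", "dance_over_volpara", "wu_over_volpara", "dance_over_wu"],
    )
    return frame


def test_single_record_summary():
    out = summarize_ratios(_triples([[50.0, 1.0, 1.0, 1.0]]))
    row = out[(out.thickness_class == "41-60") & (out.ratio == "dance_over_volpara")]
    assert row.n.item() == 1
    assert row["min"].item() == row["max"].item() == row["mean"].item() == 1.0
    assert row.sd.item() == 0.0


def test_two_record_sample_sd_hand_oracle():
    # sample SD of {0.8, 1.2} with the n-1 denominator: sqrt(2*0.04) = 0.2828...
    out = summarize_ratios(_triples([[50.0, 0.8, 1, 1], [55.0, 1.2, 1, 1]]))
    row = out[(out.thickness_class == "41-60") & (out.ratio == "dance_over_volpara")]
    assert row["mean"].item() == pytest.approx(1.0)
    assert row.sd.item() == pytest.approx(np.sqrt(0.08), abs=1e-12)


def test_thickness_class_rounding_rule():
    # fractional thickness is rounded to integer mm (round-half-even) first
    assert thickness_class(40.4) == "20-40"
    assert thickness_class(40.5) == "20-40"   # round(40.5) -> 40
    assert thickness_class(40.6) == "41-60"
    assert thickness_class(80.6) == ">80"
    # below the tabulated classes: assigned to the lowest with a warning
    assert thickness_class(18.0) == "20-40"


def test_summary_is_order_invariant(small_cohort, tables):
    records, _ = small_cohort
    res = AGDComparison.from_records(records, tables=tables).fit()
    shuffled = res.agd_table.sample(frac=1.0, random_state=1)
    a = summarize_ratios(res.agd_table).reset_index(drop=True)
    b = summarize_ratios(shuffled).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_density_category_binning():
    assert list(density_categories([10, 30, 60, 90])) == [1, 1, 1, 1]
    assert list(density_categories([12, 12, 12])) == [3, 0, 0, 0]
    # boundary values fall in the lower bin; exact zero goes to category 1
    assert list(density_categories([0, 25, 50, 75, 100])) == [2, 1, 1, 1]
    with pytest.raises(ValueError, match="outside"):
        density_categories([120.0])


def test_regression_exact_on_noiseless_plane():
    rng = np.random.default_rng(0)
    age = rng.uniform(20, 80, 50)
    t = rng.uniform(20, 100, 50)
    frame = pd.DataFrame(
        {"age": age, "thickness_mm": t, "volpara_gpw": 60 - 0.3 * age - 0.4 * t}
    )
    fit = fit_glandularity_regression(frame)
    assert fit.intercept == pytest.approx(60, abs=1e-9)
    assert fit.age_coef == pytest.approx(-0.3, abs=1e-12)
    assert fit.thickness_coef == pytest.approx(-0.4, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)


def test_regression_constant_response_gives_zero_slopes():
    rng = np.random.default_rng(1)
    frame = pd.DataFrame(
        {
            "age": rng.uniform(20, 80, 30),
            "thickness_mm": rng.uniform(20, 100, 30),
            "volpara_gpw": np.full(30, 42.0),
        }
    )
    fit = fit_glandularity_regression(frame)
    assert fit.age_coef == pytest.approx(0.0, abs=1e-12)
    assert fit.thickness_coef == pytest.approx(0.0, abs=1e-12)
    assert fit.r_squared == 0.0


def test_regression_rank_deficiency_and_input_checks():
    frame = pd.DataFrame(
        {"age": [50.0] * 10, "thickness_mm": [50.0] * 10, "volpara_gpw": np.arange(10.0)}
    )
    with pytest.raises(np.linalg.LinAlgError):
        fit_glandularity_regression(frame)
    with pytest.raises(ValueError, match="volpara_gpw"):
        fit_glandularity_regression(frame.drop(columns=["volpara_gpw"]))


def test_pearson_hand_oracle():
    frame = pd.DataFrame({"x": [1, 2, 3, 4], "r": [1, 3, 2, 4]})
    r, p = ratio_covariate_correlation(frame, "r", "x")
    assert r == pytest.approx(0.8)
    r, _ = ratio_covariate_correlation(
        pd.DataFrame({"x": [1, 2, 3, 4], "r": [2, 4, 6, 8]}), "r", "x"
    )
    assert r == pytest.approx(1.0)
    with pytest.raises(ValueError, match="zero variance"):
        ratio_covariate_correlation(
            pd.DataFrame({"x": [1, 2, 3], "r": [1, 1, 1]}), "r", "x"
        )


def test_model_fit_produces_full_results(small_cohort, tables):
    records, _ = small_cohort
    res = AGDComparison.from_records(records, tables=tables).fit()
    assert len(res.agd_table) == len(records)
    assert res.ratio_summary.n.sum() == 3 * len(records)  # three ratios per record
    assert res.regression is not None
    assert res.density_category_counts[["dance", "volpara"]].to_numpy().sum() == 2 * len(records)
    text = res.summary()
    assert "AGD ratios by thickness class" in text
    assert "Glandularity ~ age + thickness" in text
    # closure identity holds for every record
    closure = res.agd_table.dance_over_wu * res.agd_table.wu_over_volpara
    assert np.allclose(closure, res.agd_table.dance_over_volpara, rtol=1e-12)


def test_empty_inputs_rejected():
    with pytest.raises(ValueError, match="empty"):
        summarize_ratios(_triples([]))
    with pytest.raises(ValueError, match="empty"):
        AGDComparison(pd.DataFrame())


def test_vendor_density_bin_preset():
    # volumetric-grade cutpoints at 4.5 / 7.5 / 15.5 percent
    counts = density_categories([2.0, 5.0, 10.0, 40.0], bins="vendor")
    assert list(counts) == [1, 1, 1, 1]
    with pytest.raises(ValueError, match="preset"):
        density_categories([1.0], bins="birads")
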