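"""Outlier ensemble, distribution screening, and regression baselines."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hyrim.synth import generate_wqv_table
from hyrim.tabular import (
    MLR_FIXTURES,
    TWO_DPR_FIXTURES,
    backward_eliminate,
    build_2dpr_terms,
    design_matrix,
    distribution_report,
    ensemble_outliers,
    evaluate_terms,
    fit_2dpr,
    model_to_frame,
    predict_fixed,
    term_class,
)


# ---------------------------------------------------------------------- #
# outlier ensemble


def test_planted_outliers_detected():
    df, planted = generate_wqv_table(80, outlier_fraction=0.05, seed=1)
    report = ensemble_outliers(df, seed=0)
    assert set(planted) <= set(report.removed_index)
    assert report.n_removed == len(report.removed_index)
    assert len(report.surviving) == len(df) - report.n_removed


def test_outlier_flags_structure():
    df, _ = generate_wqv_table(60, seed=2)
    report = ensemble_outliers(df, seed=0)
    assert list(report.flags.columns) == ["zscore", "isolation_forest", "lof",
                                          "votes", "removed"]
    assert (report.flags["votes"] ==
            report.flags[["zscore", "isolation_forest", "lof"]].sum(axis=1)).all()
    assert (report.flags["removed"] == (report.flags["votes"] >= 2)).all()


def test_outlier_constant_column_skipped():
    df, _ = generate_wqv_table(40, seed=3)
    df["const"] = 1.0
    with pytest.warns(UserWarning, match="const"):
        report = ensemble_outliers(df, seed=0)
    assert report.skipped_columns == ["const"]


def test_outlier_too_few_rows():
    df, _ = generate_wqv_table(15, seed=0)
    with pytest.raises(ValueError):
        ensemble_outliers(df, lof_neighbors=20)


def test_outlier_deterministic():
    df, _ = generate_wqv_table(60, outlier_fraction=0.05, seed=4)
    a = ensemble_outliers(df, seed=9)
    b = ensemble_outliers(df, seed=9)
    assert (a.removed_index == b.removed_index).all()


# ---------------------------------------------------------------------- #
# distribution screening


def test_distribution_report_contents():
    df, _ = generate_wqv_table(60, seed=5)
    groups = {"zone": pd.Series(["a"] * 30 + ["b"] * 30, index=df.index)}
    rep = distribution_report(df, groups=groups, n_qq_points=10)
    shapiro = rep[rep["test"] == "shapiro_wilk"]
    assert set(shapiro["variable"]) == set(df.columns)
    assert shapiro["p_value"].notna().all()
    qq = rep[rep["test"] == "qq_point"]
    assert len(qq) == 10 * df.shape[1]
    for test in ("levene", "kruskal_wallis"):
        sub = rep[rep["test"] == test]
        assert len(sub) == df.shape[1]
        assert sub["p_value"].notna().all()


def test_distribution_report_small_group_skipped():
    df, _ = generate_wqv_table(20, seed=6)
    labels = pd.Series(["a"] * 18 + ["b"] * 2, index=df.index)
    rep = distribution_report(df, groups={"g": labels})
    lev = rep[(rep["test"] == "levene") & (rep["variable"] == "T")]
    assert lev["p_value"].isna().all()
    assert "skipped" in lev["note"].iloc[0]


# ---------------------------------------------------------------------- #
# terms and design matrices


def test_build_2dpr_term_counts():
    assert len(build_2dpr_terms(["T", "Tu", "NO3", "DO", "TS", "FC"])) == 27
    assert len(build_2dpr_terms(["T", "DO"])) == 5  # T, DO, T^2, DO^2, T*DO


def test_term_classes():
    assert term_class("T") == "linear"
    assert term_class("T^2") == "quadratic"
    assert term_class("T*DO") == "interaction"
    assert term_class("Intercept") == "intercept"


def test_design_matrix_and_evaluate_terms():
    df = pd.DataFrame({"T": [2.0], "DO": [3.0]})
    x = design_matrix(["T", "T^2", "T*DO"], df)
    assert x.loc[0, "Intercept"] == 1.0
    assert x.loc[0, "T^2"] == 4.0
    assert x.loc[0, "T*DO"] == 6.0
    val = evaluate_terms({"Intercept": 1.0, "T": 2.0, "T*DO": 0.5}, df)
    assert val[0] == pytest.approx(1.0 + 4.0 + 3.0)


# ---------------------------------------------------------------------- #
# backward elimination


def test_backward_elimination_recovers_signal():
    df, _ = generate_wqv_table(400, seed=0)
    model = backward_eliminate(df.drop(columns=["BOD5"]), df["BOD5"],
                               alpha=0.001)
    assert set(model.terms) == {"T", "DO"}
    assert model.coefficients["T"] == pytest.approx(0.5, abs=0.05)
    assert model.coefficients["DO"] == pytest.approx(-0.8, abs=0.1)
    assert model.r2 is not None and model.r2 > 0.8
    assert set(model.eliminated) == {"Tu", "NO3", "TS"}


def test_backward_elimination_keeps_intercept():
    df, _ = generate_wqv_table(200, true_coefficients={"Intercept": 100.0},
                               noise_sd=1.0, seed=1)
    model = backward_eliminate(df.drop(columns=["BOD5"]), df["BOD5"], alpha=0.001)
    assert model.terms == []
    assert model.coefficients["Intercept"] == pytest.approx(100.0, abs=0.5)


def test_backward_elimination_collinear_dropped():
    df, _ = generate_wqv_table(100, seed=2)
    df["T2"] = df["T"] * 2.0  # exact collinearity
    with pytest.warns(UserWarning, match="collinear"):
        model = backward_eliminate(df.drop(columns=["BOD5"]), df["BOD5"],
                                   alpha=0.001)
    assert "T" in model.terms and "T2" not in model.terms


def test_backward_elimination_needs_rows():
    df, _ = generate_wqv_table(30, seed=3)
    with pytest.raises(ValueError):
        backward_eliminate(df.drop(columns=["BOD5"]).head(4), df["BOD5"].head(4))


def test_fit_2dpr_full_and_pruned():
    df, _ = generate_wqv_table(300, true_coefficients={
        "Intercept": 1.0, "T": 0.3, "T^2": 0.05}, noise_sd=0.5, seed=4,
        predictors=("T", "DO"))
    full = fit_2dpr(df[["T", "DO"]], df["BOD5"], alpha=1.0)
    assert len(full.terms) == 5
    pruned = fit_2dpr(df[["T", "DO"]], df["BOD5"], alpha=0.001)
    assert {"T", "T^2"} <= set(pruned.terms)


# ---------------------------------------------------------------------- #
# published fixtures


def test_mlr_fixture_intercepts_at_zero_input():
    zeros = pd.DataFrame({c: [0.0] for c in ("T", "Tu", "NO3", "DO", "TS")})
    assert predict_fixed(MLR_FIXTURES["main_river"], zeros)[0] == -19.19
    assert predict_fixed(MLR_FIXTURES["fan_zone"], zeros)[0] == -6.67
    assert predict_fixed(MLR_FIXTURES["estuary"], zeros)[0] == 90.29


def test_2dpr_fixture_structure():
    assert set(TWO_DPR_FIXTURES) == {"full", "no_fc", "no_no3", "cost_effective"}
    assert len(TWO_DPR_FIXTURES["full"].terms) == 27
    assert TWO_DPR_FIXTURES["full"].intercept == 0.0
    assert TWO_DPR_FIXTURES["no_fc"].intercept == 35.85
    assert TWO_DPR_FIXTURES["no_no3"].intercept == -17.5383
    assert TWO_DPR_FIXTURES["cost_effective"].intercept == -28.7892


def test_2dpr_fixture_evaluates():
    cols = ("T", "Tu", "NO3", "DO", "TS", "FC")
    table = pd.DataFrame({c: [10.0, 20.0] for c in cols})
    for model in TWO_DPR_FIXTURES.values():
        vals = predict_fixed(model, table)
        assert np.isfinite(vals).all()


def test_model_to_frame():
    frame = model_to_frame(MLR_FIXTURES["main_river"])
    assert list(frame.columns) == ["term", "class", "coefficient"]
    assert frame.loc[0, "term"] == "Intercept"
    assert frame.loc[0, "coefficient"] == -19.19
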