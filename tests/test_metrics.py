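"""Closed-form checks of the evaluation-metric suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from hyrim.metrics import (
    METRIC_COLUMNS,
    brier_decomposition,
    full_report,
    interval_metrics,
    pinball_loss,
    point_metrics,
    probabilistic_metrics,
    taylor_statistics,
)


# ---------------------------------------------------------------------- #
# point metrics


def test_perfect_prediction_identities():
    o = np.array([1.0, 2.0, 5.0])
    rep = point_metrics(o, o)
    assert rep.values["R2"] == pytest.approx(1.0)
    for k in ("MSE", "RMSE", "MAE", "MAPE", "SMAPE", "MSLE"):
        assert rep.values[k] == pytest.approx(0.0, abs=1e-15)


def test_point_metrics_hand_values():
    rep = point_metrics([2.0, 4.0], [4.0, 2.0])
    assert rep.values["MSE"] == pytest.approx(4.0)
    assert rep.values["RMSE"] == pytest.approx(2.0)
    assert rep.values["MAE"] == pytest.approx(2.0)
    # R2 = 1 - 8/2 = -3 (worse than the mean predictor)
    assert rep.values["R2"] == pytest.approx(-3.0)
    # MAPE = 100 * mean(2/2, 2/4) = 75
    assert rep.values["MAPE"] == pytest.approx(75.0)
    # SMAPE = 100 * mean(2/3, 2/3) = 66.67
    assert rep.values["SMAPE"] == pytest.approx(200.0 / 3.0)


def test_mape_excludes_zero_observations():
    rep = point_metrics([0.0, 4.0], [1.0, 2.0])
    assert rep.values["MAPE"] == pytest.approx(50.0)
    assert "MAPE" in rep.notes


def test_r2_undefined_for_constant_observations():
    rep = point_metrics([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])
    assert rep.values["R2"] is None
    assert "R2" in rep.notes


def test_msle_log1p():
    o, p = np.array([1.0, 3.0]), np.array([2.0, 3.0])
    rep = point_metrics(o, p)
    expected = np.mean((np.log1p(o) - np.log1p(p)) ** 2)
    assert rep.values["MSLE"] == pytest.approx(float(expected))


def test_length_mismatch_raises():
    with pytest.raises(ValueError):
        point_metrics([1.0, 2.0], [1.0])


# ---------------------------------------------------------------------- #
# interval metrics


def test_interval_metrics_hand_values():
    o = np.array([1.0, 2.0, 3.0, 10.0])
    lo = o - 1.0
    hi = o + 1.0
    hi[3] = 9.5  # last observation falls outside
    lo[3] = 7.5
    rep = interval_metrics(o, lo, hi)
    assert rep.values["PICP"] == pytest.approx(0.75)
    assert rep.values["MPIW"] == pytest.approx(2.0)
    assert rep.values["NMPIW"] == pytest.approx(2.0 / 9.0)


def test_cwc_equals_mpiw_at_full_coverage():
    o = np.array([1.0, 2.0, 3.0])
    rep = interval_metrics(o, o - 1, o + 1, nominal=0.95)
    assert rep.values["PICP"] == 1.0
    assert rep.values["CWC"] == pytest.approx(rep.values["MPIW"])


def test_cwc_inflates_below_nominal():
    o = np.array([0.0, 0.0, 0.0, 100.0])
    rep = interval_metrics(o, [-1, -1, -1, -1], [1, 1, 1, 1], nominal=0.95,
                           eta=50.0)
    picp, mpiw = rep.values["PICP"], rep.values["MPIW"]
    expected = mpiw * (1 + math.exp(-50.0 * (picp - 0.95)))
    assert rep.values["CWC"] == pytest.approx(expected)
    assert rep.values["CWC"] > mpiw


def test_interval_bounds_validated():
    with pytest.raises(ValueError):
        interval_metrics([1.0], [2.0], [1.0])


# ---------------------------------------------------------------------- #
# probabilistic metrics


def test_nll_closed_form_at_mean():
    # obs = mean: NLL = 0.5 * ln(2 pi sigma^2)
    sigma = 1.0
    rep = probabilistic_metrics([5.0, 5.0], [5.0, 5.0], sigma)
    assert rep.values["NLL"] == pytest.approx(0.5 * math.log(2 * math.pi))


def test_crps_closed_form_at_mean():
    # z = 0: CRPS = sigma * (2 phi(0) - 1/sqrt(pi))
    sigma = 2.0
    rep = probabilistic_metrics([5.0, 5.0], [5.0, 5.0], sigma)
    expected = sigma * (2.0 / math.sqrt(2 * math.pi) - 1.0 / math.sqrt(math.pi))
    assert rep.values["CRPS"] == pytest.approx(expected)


def test_crps_degenerate_equals_absolute_error():
    rep = probabilistic_metrics([5.0, 8.0], [4.0, 10.0], 0.0)
    assert rep.values["CRPS"] == pytest.approx(1.5)
    assert rep.values["NLL"] is None


def test_crps_oracle_numeric_integration():
    # CRPS(F, y) = int (F(x) - 1[x >= y])^2 dx, numerically for one Gaussian
    from scipy import stats

    mu, sigma, y = 1.0, 1.5, 2.3
    # split the domain at the step discontinuity for an accurate quadrature
    left = np.linspace(mu - 14 * sigma, y, 100001)
    right = np.linspace(y, mu + 14 * sigma, 100001)
    oracle = np.trapezoid(stats.norm.cdf(left, mu, sigma) ** 2, left)
    oracle += np.trapezoid((stats.norm.cdf(right, mu, sigma) - 1.0) ** 2, right)
    rep = probabilistic_metrics([y, y], [mu, mu], sigma)
    assert rep.values["CRPS"] == pytest.approx(oracle, rel=1e-6)


def test_negative_sd_raises():
    with pytest.raises(ValueError):
        probabilistic_metrics([1.0], [1.0], -0.5)


# ---------------------------------------------------------------------- #
# pinball loss


def test_pinball_median_is_half_mae():
    o = np.array([1.0, 4.0, 9.0])
    q = np.array([2.0, 2.0, 2.0])
    out = pinball_loss(o, {0.5: q}, levels=None)
    mae = np.mean(np.abs(o - q))
    assert out[0.5] == pytest.approx(mae / 2.0)


def test_pinball_asymmetry_and_validation():
    o = np.array([2.0, 2.0])
    q = np.array([0.0, 0.0])  # under-prediction
    out = pinball_loss(o, np.array([q, q]), levels=[0.1, 0.9])
    assert out[0.9] == pytest.approx(9.0 * out[0.1])
    with pytest.raises(ValueError):
        pinball_loss(o, {1.5: q}, levels=None)


# ---------------------------------------------------------------------- #
# Brier decomposition


def test_brier_identity_and_oracle(rng):
    y = (rng.random(500) < 0.4).astype(float)
    p = rng.random(500)
    scores, curve = brier_decomposition(y, p, n_bins=10)
    assert scores["BS"] == pytest.approx(
        scores["UNC"] + scores["REL"] - scores["RES"], abs=1e-12
    )
    # brute-force oracle over the same equal-width bins
    edges = np.linspace(0, 1, 11)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, 9)
    base = y.mean()
    rel = sum((p[idx == b].mean() - y[idx == b].mean()) ** 2 * (idx == b).sum()
              for b in range(10) if (idx == b).any()) / y.size
    res = sum((y[idx == b].mean() - base) ** 2 * (idx == b).sum()
              for b in range(10) if (idx == b).any()) / y.size
    assert scores["REL"] == pytest.approx(rel, abs=1e-12)
    assert scores["RES"] == pytest.approx(res, abs=1e-12)
    assert scores["UNC"] == pytest.approx(base * (1 - base), abs=1e-12)
    assert set(curve.columns) == {"bin", "mean_probability",
                                  "observed_frequency", "count"}
    assert curve["count"].sum() == 500


def test_brier_validation():
    with pytest.raises(ValueError):
        brier_decomposition([0, 2], [0.5, 0.5])
    with pytest.raises(ValueError):
        brier_decomposition([0, 1], [0.5, 1.5])


# ---------------------------------------------------------------------- #
# Taylor statistics


def test_taylor_law_of_cosines(rng):
    o = rng.normal(size=200)
    p = 0.6 * o + rng.normal(size=200)
    t = taylor_statistics(o, p)
    lhs = t["crmsd"] ** 2
    rhs = (t["sd_observed"] ** 2 + t["sd_predicted"] ** 2
           - 2 * t["sd_observed"] * t["sd_predicted"] * t["correlation"])
    assert lhs == pytest.approx(rhs, rel=1e-10)


def test_taylor_perfect_prediction():
    o = np.array([1.0, 2.0, 3.0])
    t = taylor_statistics(o, o)
    assert t["sd_ratio"] == pytest.approx(1.0)
    assert t["correlation"] == pytest.approx(1.0)
    assert t["crmsd"] == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------- #
# assembled report


def test_full_report_columns_and_frame(rng):
    o = rng.normal(10, 2, size=50)
    p = o + rng.normal(0, 0.5, size=50)
    rep = full_report(o, p, lower=p - 2, upper=p + 2, predictive_sd=0.5)
    for col in METRIC_COLUMNS:
        assert col in rep.values, col
    frame = rep.to_frame("hyrim")
    assert list(frame.columns) == METRIC_COLUMNS
    assert frame.index[0] == "hyrim"
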