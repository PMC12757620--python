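"""Point, interval, and probabilistic evaluation metrics.

Covers the full suite used to compare the interpolation model against
regression baselines: R2, MSE, RMSE, MAE, MAPE, SMAPE, MSLE for point
forecasts; PICP, MPIW, NMPIW and the composite coverage-width criterion
(CWC) for prediction intervals; Gaussian NLL and CRPS plus pinball loss for
probabilistic forecasts; the Murphy decomposition of the Brier score for
threshold-exceedance forecasts; and Taylor-diagram statistics.

Conventions: MAPE and SMAPE are on the 0-100 percent scale; SMAPE uses the
(|o| + |p|)/2 denominator and is bounded by 200. CWC follows the
MPIW-scaled coverage-width criterion

    CWC = MPIW * (1 + 1[PICP < nominal] * exp(-eta * (PICP - nominal)))

with eta = 50 by default, so CWC equals MPIW whenever coverage meets the
nominal level and inflates exponentially as coverage falls short.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricReport",
    "point_metrics",
    "interval_metrics",
    "probabilistic_metrics",
    "pinball_loss",
    "brier_decomposition",
    "taylor_statistics",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "R2", "MSE", "RMSE", "MAE", "MAPE", "SMAPE", "MSLE",
    "PICP", "MPIW", "NMPIW", "CWC", "NLL", "CRPS",
]


@dataclass
class MetricReport:
    """One model's metric values; missing entries are None with a reason."""

    values: dict[str, float | None] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def update(self, other: "MetricReport") -> "MetricReport":
        self.values.update(other.values)
        self.notes.update(other.notes)
        return self

    def to_frame(self, model: str = "model") -> pd.DataFrame:
        row = {c: self.values.get(c) for c in METRIC_COLUMNS}
        return pd.DataFrame([row], index=pd.Index([model], name="model"))


def _paired(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError(f"length mismatch: {o.shape} vs {p.shape}")
    if o.size < 2:
        raise ValueError("need at least 2 paired samples")
    return o, p


def point_metrics(observed, predicted) -> MetricReport:
    """R2, MSE, RMSE, MAE, MAPE, SMAPE, MSLE for paired samples.

    Observations equal to zero are excluded from MAPE (count recorded in the
    notes). MSLE requires all values > -1. A constant observed vector leaves
    R2 undefined (None, with a reason).
    """
    o, p = _paired(observed, predicted)
    rep = MetricReport()
    err = o - p
    mse = float(np.mean(err**2))
    rep.values["MSE"] = mse
    rep.values["RMSE"] = math.sqrt(mse)
    rep.values["MAE"] = float(np.mean(np.abs(err)))

    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        rep.values["R2"] = None
        rep.notes["R2"] = "undefined: observed vector is constant"
    else:
        rep.values["R2"] = 1.0 - float(np.sum(err**2)) / ss_tot

    nonzero = o != 0
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        rep.notes["MAPE"] = f"{n_excluded} zero observations excluded"
    if nonzero.any():
        rep.values["MAPE"] = float(
            100.0 * np.mean(np.abs(err[nonzero] / o[nonzero]))
        )
    else:
        rep.values["MAPE"] = None
        rep.notes["MAPE"] = "undefined: all observations are zero"

    denom = (np.abs(o) + np.abs(p)) / 2.0
    smape_terms = np.where(denom > 0, np.abs(err) / np.where(denom > 0, denom, 1.0), 0.0)
    rep.values["SMAPE"] = float(100.0 * np.mean(smape_terms))

    if np.all(o > -1) and np.all(p > -1):
        rep.values["MSLE"] = float(np.mean((np.log1p(o) - np.log1p(p)) ** 2))
    else:
        rep.values["MSLE"] = None
        rep.notes["MSLE"] = "undefined: values <= -1 present"
    return rep


def interval_metrics(
    observed, lower, upper, nominal: float = 0.95, eta: float = 50.0
) -> MetricReport:
    """PICP, MPIW, NMPIW and CWC for elementwise prediction intervals."""
    o = np.asarray(observed, dtype=float)
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    if not (o.shape == lo.shape == hi.shape):
        raise ValueError("observed/lower/upper must have equal shapes")
    if np.any(lo > hi):
        raise ValueError("lower bound exceeds upper bound")
    rep = MetricReport()
    picp = float(np.mean((o >= lo) & (o <= hi)))
    mpiw = float(np.mean(hi - lo))
    rep.values["PICP"] = picp
    rep.values["MPIW"] = mpiw
    obs_range = float(o.max() - o.min())
    if obs_range > 0:
        rep.values["NMPIW"] = mpiw / obs_range
    else:
        rep.values["NMPIW"] = None
        rep.notes["NMPIW"] = "undefined: zero observed range"
    penalty = math.exp(-eta * (picp - nominal)) if picp < nominal else 0.0
    rep.values["CWC"] = mpiw * (1.0 + penalty)
    return rep


def probabilistic_metrics(observed, mean, sd) -> MetricReport:
    """Gaussian NLL and CRPS averaged over samples.

    With sd = 0 the forecast is degenerate: CRPS reduces to the absolute
    error and NLL is undefined (None).
    """
    o = np.asarray(observed, dtype=float)
    mu = np.broadcast_to(np.asarray(mean, dtype=float), o.shape)
    s = np.broadcast_to(np.asarray(sd, dtype=float), o.shape).copy()
    if np.any(s < 0):
        raise ValueError("predictive sd must be >= 0")
    rep = MetricReport()
    degenerate = s == 0
    crps = np.empty_like(o)
    crps[degenerate] = np.abs(o - mu)[degenerate]
    if (~degenerate).any():
        z = (o[~degenerate] - mu[~degenerate]) / s[~degenerate]
        crps[~degenerate] = s[~degenerate] * (
            z * (2.0 * stats.norm.cdf(z) - 1.0)
            + 2.0 * stats.norm.pdf(z)
            - 1.0 / math.sqrt(math.pi)
        )
    rep.values["CRPS"] = float(np.mean(crps))
    if degenerate.any():
        rep.values["NLL"] = None
        rep.notes["NLL"] = "undefined: degenerate (sd = 0) forecasts present"
    else:
        nll = 0.5 * np.log(2.0 * math.pi * s**2) + (o - mu) ** 2 / (2.0 * s**2)
        rep.values["NLL"] = float(np.mean(nll))
    return rep


def pinball_loss(observed, quantile_predictions, levels) -> dict[float, float]:
    """Mean pinball (quantile) loss per level.

    quantile_predictions : array (n_levels, n) or mapping level -> array.
    """
    o = np.asarray(observed, dtype=float)
    if isinstance(quantile_predictions, dict):
        items = [(float(k), np.asarray(v, float)) for k, v in
                 quantile_predictions.items()]
    else:
        qp = np.asarray(quantile_predictions, dtype=float)
        items = [(float(t), qp[i]) for i, t in enumerate(levels)]
    out: dict[float, float] = {}
    for tau, q in items:
        if not 0.0 < tau < 1.0:
            raise ValueError(f"quantile level {tau} outside (0, 1)")
        diff = o - q
        out[tau] = float(np.mean(np.where(diff >= 0, tau * diff, (tau - 1) * diff)))
    return out


def brier_decomposition(
    outcomes, probabilities, n_bins: int = 10
) -> tuple[dict[str, float], pd.DataFrame]:
    """Brier score and its Murphy decomposition over equal-width bins.

    Returns (scores, reliability_curve) where scores holds BS, uncertainty
    (UNC), reliability (REL) and resolution (RES) with the exact identity
    BS = UNC + REL - RES on the binned statistics, and the curve table gives
    per-bin mean forecast probability, observed frequency and count
    (empty bins omitted).
    """
    y = np.asarray(outcomes, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("outcomes must be binary 0/1")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    n = y.size
    base = float(y.mean())
    unc = base * (1.0 - base)

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    rel = res = 0.0
    for b in range(n_bins):
        sel = idx == b
        nk = int(sel.sum())
        if nk == 0:
            continue
        pk = float(p[sel].mean())
        ok = float(y[sel].mean())
        rel += nk * (pk - ok) ** 2
        res += nk * (ok - base) ** 2
        rows.append({"bin": b, "mean_probability": pk,
                     "observed_frequency": ok, "count": nk})
    rel /= n
    res /= n
    # BS computed on binned forecasts so the identity holds exactly
    p_binned = np.empty_like(p)
    for row in rows:
        p_binned[idx == row["bin"]] = row["mean_probability"]
    bs = float(np.mean((p_binned - y) ** 2))
    scores = {
        "BS": bs,
        "BS_raw": float(np.mean((p - y) ** 2)),
        "UNC": unc,
        "REL": rel,
        "RES": res,
    }
    return scores, pd.DataFrame(rows)


def taylor_statistics(observed, predicted) -> dict[str, float]:
    """Taylor-diagram triple: sd ratio, Pearson r, centered RMS difference."""
    o, p = _paired(observed, predicted)
    so = float(np.std(o))
    sp = float(np.std(p))
    oc, pc = o - o.mean(), p - p.mean()
    denom = so * sp * o.size
    r = float(np.sum(oc * pc) / denom) if denom > 0 else float("nan")
    crms = float(np.sqrt(np.mean((pc - oc) ** 2)))
    return {
        "sd_ratio": sp / so if so > 0 else float("nan"),
        "correlation": r,
        "crmsd": crms,
        "sd_observed": so,
        "sd_predicted": sp,
    }


def full_report(
    observed,
    predicted,
    lower=None,
    upper=None,
    predictive_sd=None,
    nominal: float = 0.95,
) -> MetricReport:
    """Assemble the 13-metric report for one model on one dataset.

    If interval bounds are omitted the interval metrics stay missing; the
    predictive distribution for NLL/CRPS is Gaussian centered at the point
    prediction with the supplied sd (scalar or per-sample), defaulting to
    the sd of the residuals.
    """
    rep = point_metrics(observed, predicted)
    if lower is not None and upper is not None:
        rep.update(interval_metrics(observed, lower, upper, nominal=nominal))
    o = np.asarray(observed, float)
    p = np.asarray(predicted, float)
    sd = predictive_sd if predictive_sd is not None else float(np.std(o - p))
    rep.update(probabilistic_metrics(o, p, sd))
    return rep
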