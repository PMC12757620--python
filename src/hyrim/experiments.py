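"""Sensitivity analysis and monitoring-network reduction experiments.

One-at-a-time (OAT) sensitivity: each of the four hyperparameters is varied
by +/-10%, +/-25% and +/-50% around its calibrated optimum (24 scenarios)
and the leave-one-out RMSE is re-evaluated with the other parameters held
fixed. Network reduction: random subsets of stations are retained, the
remaining ("unmonitored") stations are predicted from them, and the RMSE
trajectory versus retained-station count quantifies how gracefully accuracy
degrades as the monitoring network shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import calibrate, loocv_rmse
from .model import DEFAULT_DIRECTION_WEIGHTS, DirectionWeights, HyperParams, BOUNDS, predict_matrix
from .network import PairwiseFeatures, RiverNetwork, pairwise_features

__all__ = [
    "SensitivityScenario",
    "ReductionPoint",
    "oat_sensitivity",
    "network_reduction",
    "OAT_VARIATIONS",
]

OAT_VARIATIONS = (-0.50, -0.25, -0.10, 0.10, 0.25, 0.50)
PARAM_NAMES = ("alpha", "beta", "gamma", "delta")


@dataclass
class SensitivityScenario:
    parameter: str
    variation: float  # relative, e.g. -0.25
    new_value: float
    rmse: float
    pct_change: float  # 100 * (rmse - rmse_opt) / rmse_opt
    clipped: bool = False
    degenerate: bool = False  # zero-valued optimum: relative step is a no-op


@dataclass
class ReductionPoint:
    n_retained: int
    mean_rmse: float
    sd_rmse: float
    n_iter: int


def _loocv_rmse_at(
    feats: PairwiseFeatures,
    params: HyperParams,
    direction_weights: DirectionWeights,
    eval_mask: np.ndarray | None,
) -> float:
    pred = predict_matrix(feats, params, direction_weights)
    return loocv_rmse(feats.bod5, pred, eval_mask)


def oat_sensitivity(
    network: RiverNetwork,
    optimal: HyperParams,
    station_ids: list[str] | None = None,
    direction_weights: DirectionWeights = DEFAULT_DIRECTION_WEIGHTS,
    time_unit: str = "hours",
    eval_station_ids: list[str] | None = None,
    variations: tuple[float, ...] = OAT_VARIATIONS,
) -> tuple[list[SensitivityScenario], float]:
    """24 one-at-a-time scenarios around the calibrated optimum.

    Perturbed values falling outside the physical bounds are clipped and
    flagged; a zero-valued optimal parameter makes its relative perturbation
    degenerate (flagged, not skipped). Returns (scenarios, optimal RMSE).
    """
    feats = pairwise_features(
        network,
        station_ids if station_ids is not None else
        [s for s in network.stations if network.stations[s].bod5 is not None],
        time_unit,
    )
    eval_mask = None
    if eval_station_ids is not None:
        eval_mask = np.isin(feats.station_ids, list(eval_station_ids))
    rmse_opt = _loocv_rmse_at(feats, optimal, direction_weights, eval_mask)

    scenarios: list[SensitivityScenario] = []
    base = {name: getattr(optimal, name) for name in PARAM_NAMES}
    for name in PARAM_NAMES:
        lo, hi = BOUNDS[name]
        for var in variations:
            raw = base[name] * (1.0 + var)
            new = float(np.clip(raw, lo, hi))
            params = HyperParams(**{**base, name: new})
            rmse = _loocv_rmse_at(feats, params, direction_weights, eval_mask)
            scenarios.append(
                SensitivityScenario(
                    parameter=name,
                    variation=var,
                    new_value=new,
                    rmse=rmse,
                    pct_change=100.0 * (rmse - rmse_opt) / rmse_opt
                    if rmse_opt > 0 else float("nan"),
                    clipped=(new != raw),
                    degenerate=(base[name] == 0.0),
                )
            )
    return scenarios, rmse_opt


def sensitivity_to_frame(scenarios: list[SensitivityScenario]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in scenarios])


def network_reduction(
    network: RiverNetwork,
    sizes: list[int],
    n_iter: int = 50,
    seed: int = 0,
    params: HyperParams = HyperParams(),
    direction_weights: DirectionWeights = DEFAULT_DIRECTION_WEIGHTS,
    time_unit: str = "hours",
    recalibrate: bool = False,
    n_starts: int = 4,
) -> list[ReductionPoint]:
    """Random-subset monitoring-network reduction simulation.

    For each retained-station count, ``n_iter`` seeded subsets are drawn
    uniformly without replacement; held-out stations are predicted from the
    retained ones (at fixed ``params`` by default, or recalibrating per
    subset) and the per-iteration RMSE over held-out stations is aggregated
    to a mean +/- sd per size.
    """
    ids = [s for s in network.stations if network.stations[s].bod5 is not None]
    n = len(ids)
    for size in sizes:
        if size < 3:
            raise ValueError(f"retained size {size} < 3")
        if size > n:
            raise ValueError(f"retained size {size} exceeds {n} available stations")
    feats = pairwise_features(network, ids, time_unit)
    rng = np.random.default_rng(seed)

    points: list[ReductionPoint] = []
    for size in sizes:
        rmses = np.empty(n_iter)
        for it in range(n_iter):
            keep = np.zeros(n, dtype=bool)
            keep[rng.choice(n, size=size, replace=False)] = True
            p = params
            if recalibrate:
                sub_ids = [ids[i] for i in np.nonzero(keep)[0]]
                p = calibrate(
                    network, station_ids=sub_ids, n_starts=n_starts,
                    seed=int(rng.integers(2**31 - 1)),
                    direction_weights=direction_weights, time_unit=time_unit,
                ).params
            mask = np.broadcast_to(keep[None, :], (n, n)).copy()
            pred = predict_matrix(feats, p, direction_weights, neighbor_mask=mask)
            held = ~keep
            rmses[it] = loocv_rmse(feats.bod5[held], pred[held])
        points.append(
            ReductionPoint(
                n_retained=size,
                mean_rmse=float(rmses.mean()),
                sd_rmse=float(rmses.std(ddof=0)),
                n_iter=n_iter,
            )
        )
    return points


def reduction_to_frame(points: list[ReductionPoint]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in points])
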