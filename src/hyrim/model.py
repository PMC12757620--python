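"""Influence-weight function and weighted-average BOD5 predictor.

A neighbor station's influence on a target location is

    W = W_direction * Order**alpha / (T_t * SI**gamma)**beta

where ``Order`` is the neighbor's Strahler stream order, ``T_t`` the
advective travel time along the connecting channel path, ``SI`` the path's
sinuosity index, and ``W_direction`` a categorical weight for the flow
relation (upstream inflow counts fully, downstream and disconnected
neighbors are strongly discounted, tributaries carry the calibratable
coefficient delta). The prediction at the target is the W-weighted average
of neighbor observations, hence always a convex combination of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import (
    PairwiseFeatures,
    RELATION_CODES,
    Relation,
    RiverNetwork,
    pairwise_features,
)

__all__ = [
    "HyperParams",
    "DirectionWeights",
    "NeighborFeatures",
    "influence_weight",
    "predict_bod",
    "predict_matrix",
    "DEFAULT_PARAMS",
    "TRAVEL_TIME_EPS",
]

#: Travel times below this (in the working time unit) trigger the
#: co-located shortcut instead of a divergent weight.
TRAVEL_TIME_EPS = 1e-6

#: Numeric floor below which a total weight mass is treated as underflow.
WEIGHT_FLOOR = 1e-300

BOUNDS = {"alpha": (0.0, 3.0), "beta": (0.0, 3.0), "gamma": (0.0, 3.0),
          "delta": (0.0, 1.0)}


@dataclass(frozen=True)
class HyperParams:
    """The four calibratable parameters of the weight function.

    alpha : stream-order exponent, 0..3
    beta  : effective travel-time decay exponent, 0..3
    gamma : sinuosity exponent (modifies travel time), 0..3
    delta : tributary direction coefficient, 0..1
    """

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    delta: float = 0.5

    def __post_init__(self) -> None:
        for name, (lo, hi) in BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.delta])

    @classmethod
    def from_array(cls, v: Sequence[float]) -> "HyperParams":
        return cls(*(float(x) for x in v))


#: Theoretically based pre-calibration parameter set.
DEFAULT_PARAMS = HyperParams(alpha=1.0, beta=1.0, gamma=1.0, delta=0.5)


@dataclass(frozen=True)
class DirectionWeights:
    """Categorical flow-relation weights, all in (0, 1].

    The tributary entry is replaced by the hyperparameter delta at
    evaluation time; the stored value is only a fallback.
    """

    upstream: float = 1.0
    downstream: float = 0.05
    tributary: float = 0.5
    different_branch: float = 0.01

    def __post_init__(self) -> None:
        for name in ("upstream", "downstream", "tributary", "different_branch"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"direction weight {name}={v} outside (0, 1]")

    def vector(self, delta: float | None = None) -> np.ndarray:
        """Weights indexed by relation code, with delta substituted for tributary."""
        trib = self.tributary if delta is None else delta
        if not (0.0 < trib <= 1.0):
            # delta = 0 would zero out tributaries entirely; clamp to floor
            trib = max(trib, 1e-12)
        return np.array([self.upstream, self.downstream, trib, self.different_branch])


DEFAULT_DIRECTION_WEIGHTS = DirectionWeights()


@dataclass(frozen=True)
class NeighborFeatures:
    """Features of one neighbor relative to a target location."""

    relation: Relation
    order: int
    travel_time: float  # working time unit (> 0; 0 means co-located)
    sinuosity: float
    observed_bod: float

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")
        if self.travel_time < 0:
            raise ValueError(f"travel_time must be >= 0, got {self.travel_time}")
        if self.sinuosity < 1.0 - 1e-9:
            raise ValueError(f"sinuosity must be >= 1, got {self.sinuosity}")


def influence_weight(
    f: NeighborFeatures,
    p: HyperParams = DEFAULT_PARAMS,
    d: DirectionWeights = DEFAULT_DIRECTION_WEIGHTS,
) -> float:
    """Influence weight of one neighbor; finite and strictly positive."""
    if f.travel_time <= TRAVEL_TIME_EPS:
        raise ValueError(
            "travel_time is at the co-located floor; use predict_bod, which "
            "short-circuits co-located neighbors"
        )
    w_dir = d.vector(p.delta)[RELATION_CODES[f.relation]]
    w = w_dir * f.order**p.alpha / (f.travel_time * f.sinuosity**p.gamma) ** p.beta
    if not np.isfinite(w) or w <= 0:
        raise ArithmeticError(f"non-finite or non-positive weight {w}")
    return float(w)


def predict_bod(
    neighbors: Sequence[NeighborFeatures],
    p: HyperParams = DEFAULT_PARAMS,
    d: DirectionWeights = DEFAULT_DIRECTION_WEIGHTS,
) -> float:
    """Weighted-average BOD5 prediction at a target (mg/L).

    A co-located neighbor (travel time at the numeric floor) determines the
    prediction directly. Otherwise the result is sum(W_i * BOD_i) / sum(W_i).
    """
    if not neighbors:
        raise ValueError("prediction requires at least one neighbor")
    for f in neighbors:
        if f.travel_time <= TRAVEL_TIME_EPS:
            return float(f.observed_bod)
    w = np.array([influence_weight(f, p, d) for f in neighbors])
    total = w.sum()
    if total <= WEIGHT_FLOOR:
        raise ArithmeticError(
            f"total neighbor weight underflowed below {WEIGHT_FLOOR:g}"
        )
    obs = np.array([f.observed_bod for f in neighbors])
    return float(w @ obs / total)


# ---------------------------------------------------------------------- #
# vectorized path over precomputed pairwise features


def weight_matrix(
    feats: PairwiseFeatures,
    p: HyperParams,
    d: DirectionWeights = DEFAULT_DIRECTION_WEIGHTS,
) -> np.ndarray:
    """(n, n) matrix of influence weights; W[i, j] = weight of j on target i.

    The diagonal is zero. Co-located off-diagonal pairs (travel time at the
    floor) are handled by the caller via ``predict_matrix``.
    """
    n = len(feats.station_ids)
    dir_vec = d.vector(p.delta)
    rel = feats.relation.copy()
    off = rel >= 0
    w = np.zeros((n, n))
    tt = feats.travel_time
    si = feats.sinuosity
    order = np.broadcast_to(feats.order[None, :], (n, n))
    safe_tt = np.where(off & (tt > TRAVEL_TIME_EPS), tt, 1.0)
    w[off] = (
        dir_vec[rel[off]]
        * order[off] ** p.alpha
        / (safe_tt[off] * si[off] ** p.gamma) ** p.beta
    )
    w[~off] = 0.0
    return w


def predict_matrix(
    feats: PairwiseFeatures,
    p: HyperParams,
    d: DirectionWeights = DEFAULT_DIRECTION_WEIGHTS,
    neighbor_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Predict every station from its eligible neighbors, vectorized.

    neighbor_mask : (n, n) boolean, optional
        ``mask[i, j]`` True if station j may serve as a neighbor of target i.
        Defaults to all off-diagonal pairs (the leave-one-out scheme).

    Returns the (n,) vector of predictions; NaN where a target has no
    eligible neighbor with an observation.
    """
    n = len(feats.station_ids)
    mask = ~np.eye(n, dtype=bool) if neighbor_mask is None else neighbor_mask.copy()
    np.fill_diagonal(mask, False)
    mask &= ~np.isnan(feats.bod5)[None, :]

    w = weight_matrix(feats, p, d)
    w = np.where(mask, w, 0.0)
    obs = np.where(np.isnan(feats.bod5), 0.0, feats.bod5)
    total = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pred = (w @ obs) / total
    pred[total <= WEIGHT_FLOOR] = np.nan

    # co-located shortcut: nearest zero-travel-time neighbor wins
    colocated = mask & (feats.travel_time <= TRAVEL_TIME_EPS)
    for i in np.nonzero(colocated.any(axis=1))[0]:
        j = int(np.nonzero(colocated[i])[0][0])
        pred[i] = feats.bod5[j]
    return pred


def loocv_matrix(
    network: RiverNetwork,
    station_ids: list[str] | None = None,
    time_unit: str = "hours",
) -> PairwiseFeatures:
    """Convenience: pairwise features for the stations used in LOOCV."""
    return pairwise_features(network, station_ids, time_unit)
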