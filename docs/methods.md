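# Methods

This note records the model implemented by `hyrim`, the assumptions and
parameter semantics, what the synthetic generators emulate (and what they do
not), the main numerical choices, and known limitations.

## 1. Network representation

A river monitoring network is a **dendritic tree**: junctions are nodes,
segments are directed edges following flow, every junction drains through at
most one outgoing segment, and the network has exactly one outlet. These
invariants are validated at construction (`hyrim.network.RiverNetwork`);
cycles, braided channels (out-degree > 1) and multi-outlet deltas are
rejected rather than silently accepted.

Derived per-pair features:

- **Strahler order** — headwaters are order 1; where the maximum inflowing
  order k arrives on at least two branches the downstream order is k + 1,
  otherwise k. An explicit station order supplied in the input overrides the
  derived value.
- **Hydrologic distance / travel time** — summed along the unique tree path
  between two stations; travel time is Σ (segment length / segment mean
  velocity). Internally travel time is expressed in **hours** by default
  (`time_unit="seconds"` is available); with β ≈ 0.5 the weight is merely
  rescaled by a constant factor per unit choice, which cancels in the
  weighted average, so predictions are unit-invariant — the choice matters
  only for reporting.
- **Sinuosity index** — path channel length over straight-line distance.
  SI < 1 (beyond a 1e-9 floating-point tolerance) is physically impossible
  and raises an error instead of being clamped; co-located stations get
  SI = 1.
- **Flow relation** — each ordered pair is `upstream`, `downstream`,
  `tributary`, or `different_branch`. The *mainstem* above a junction is the
  walk that follows, at each confluence, the inflow of highest Strahler
  order (ties: larger upstream channel length, then lexicographically
  smaller id). A flow-connected neighbor on the target's mainstem is
  `upstream` (mirror: `downstream`); a flow-connected neighbor joined
  through a side branch is `tributary` **symmetrically in both directions**,
  so `upstream(a, b) ⇔ downstream(b, a)` holds exactly and the tributary
  class is order-free. Stations whose sub-catchments meet only below both
  are `different_branch`.

## 2. Interpolation model

Influence of neighbor j on target i:

    W_ij = W_dir(relation) × Order_j^α / (T_t,ij × SI_ij^γ)^β

Prediction: x̂_i = Σ_j W_ij x_j / Σ_j W_ij — a convex combination of
neighbor observations. A co-located neighbor (travel time at the 1e-6
floor) determines the prediction directly rather than producing a divergent
weight.

Parameters (bounds enforced everywhere):

| parameter | role | bounds | pre-calibration default |
|---|---|---|---|
| α | stream-order amplification | [0, 3] | 1.0 |
| β | travel-time decay exponent | [0, 3] | 1.0 |
| γ | sinuosity penalty (modifies travel time) | [0, 3] | 1.0 |
| δ | tributary direction weight | [0, 1] | 0.5 |

Fixed categorical direction weights: upstream 1.0, downstream 0.05,
different-branch 0.01; the tributary entry is replaced by δ at evaluation
time. The calibrated reference set used as the synthetic generating truth is
α = 2.450, β = 0.512, γ = 0.225, δ = 1.000.

## 3. Calibration

The objective is leave-one-out cross-validation RMSE over the monitored
stations (each station predicted from all the others). It is non-convex, so
calibration runs bounded L-BFGS-B from a seeded Latin-hypercube of start
points (16 by default) and keeps the best final objective (ties broken by
smaller parameter norm). `eval_station_ids` restricts which stations' errors
enter the RMSE while all stations still serve as neighbors — used to treat
headwater stations, which have no upstream information, as boundary data
rather than validation points.

`expected_recovery_sd` provides a Fisher-information forecast of calibration
precision: linearizing the LOOCV predictions around the true parameters
gives the asymptotic covariance σ²(JᵀJ)⁻¹ of the least-squares estimate.
Parameters sitting exactly on a bound (e.g. δ = 1) are treated as fixed.
The forecast depends only on station geometry and the noiseless field, so it
can qualify a network design *before* any noisy data exist.

## 4. Synthetic generators

`generate_network` grows a random dendritic tree from the outlet: each new
junction either extends a channel tip or creates a (binary) confluence with
probability 0.4. Segment lengths (200 m – 20 km) and velocities
(0.1 – 2 m/s) are **log-uniform** — river reach lengths and flows are
heavy-tailed, and the resulting travel-time contrast is what makes the decay
exponent identifiable from a small network. Per-segment sinuosities are
uniform on [1.05, 2.5]; coordinates place each child so its straight-line
chord equals length / sinuosity, which keeps every station pair's SI ≥ 1 by
the triangle inequality.

Two BOD₅ fields:

- **Model-consistent** (`generate_bod_model_consistent`): headwater stations
  are boundary values drawn lognormally (median 8 mg/L, log-sd 0.8 —
  concentration data in mixed-use basins are canonically right-skewed);
  interior stations solve the linear system x_I = P_II x_I + P_IB b, where P
  is the row-normalized weight matrix at the true parameters. At zero noise
  every **interior** station equals its full-neighbor leave-one-out
  prediction exactly. A row-stochastic averaging operator admits no
  non-constant fixed point over *all* stations, so exact closure over
  headwaters too is mathematically impossible; the boundary/interior split
  is what makes a non-trivial exactly-closable field exist at all. Gaussian
  noise is added afterwards and values are clipped at 0.
- **Load accumulation** (`generate_bod_load_accumulation`): point loads
  decay first-order in travel time and accumulate downstream — a spatially
  autocorrelated field the interpolation model has *no* structural knowledge
  of, for out-of-model testing.

What the generators do **not** emulate: seasonal dynamics, flow-dependent
velocities, reactive transport (reaeration, temperature dependence),
measurement protocols, or spatially correlated noise. Observations are
i.i.d. Gaussian perturbations of a static field.

`find_informative_design` qualifies candidate network draws for
parameter-recovery studies: a random 20–30-station tree is not automatically
informative (stream order and travel time are topologically correlated, and
some draws leave α and β nearly collinear), so seeds are scanned until the
Fisher forecast of relative recovery sd for α and β is within a 6% budget,
evaluated on the noiseless field with noise set to 2% of the field mean.

`generate_wqv_table` produces multivariate water-quality tables
(T, Tu, NO₃, DO, TS, FC with realistic marginal means/sds) with a known
sparse response (default BOD₅ = 4 + 0.5 T − 0.8 DO + ε) and optional planted
outliers shifted 8 column-sd in every predictor.

## 5. Uncertainty

`bootstrap_ensemble` resamples the station set with replacement (duplicates
collapse — a duplicated neighbor at zero distance would otherwise dominate
the weights unphysically), optionally recalibrates the four parameters per
replicate, and predicts every original station from the replicate members
excluding itself. Because an ensemble of point predictions alone is a
confidence interval for the *predictor*, each replicate prediction also
receives one within-replicate leave-one-out residual resampled with
replacement — the classical bootstrap prediction-interval construction —
so the 2.5/97.5 percentiles form a prediction interval for the
*observation* (`prediction_noise=False` exposes the predictor spread alone).
Exceedance probability is the fraction of an ensemble strictly above the
regulatory threshold (default 10 mg/L). The default is 1,000 iterations with
per-replicate recalibration; the fast mode reuses fixed parameters.

## 6. Metrics

Point: R², MSE, RMSE, MAE, MAPE (zeros excluded, counted), SMAPE
((|o|+|p|)/2 denominator, 0–100 scale), MSLE (log1p). Interval: PICP, MPIW,
NMPIW (range-normalized) and the coverage-width criterion

    CWC = MPIW × (1 + 1[PICP < nominal] · exp(−η (PICP − nominal))),  η = 50

i.e. CWC **equals MPIW** whenever coverage meets the nominal level and
inflates exponentially as coverage falls short. (The alternative convention
scales NMPIW instead; the MPIW-based form is used so that CWC is reported in
mg/L alongside MPIW.) Probabilistic: Gaussian NLL and closed-form Gaussian
CRPS (σ[z(2Φ(z)−1) + 2φ(z) − 1/√π]; degenerate σ = 0 reduces CRPS to the
absolute error), pinball loss per quantile level, and the Murphy
decomposition of the Brier score over 10 equal-width bins — the score is
computed on bin-mean forecasts so BS = UNC + REL − RES holds exactly (the
unbinned score is reported separately as `BS_raw`). Taylor statistics
(sd ratio, correlation, centered RMS difference) complete the suite.

## 7. Experiments

- **OAT sensitivity**: each parameter varied by ±10 / ±25 / ±50% around a
  calibrated optimum (4 × 6 = 24 scenarios), others held fixed. Values
  clipped into bounds are flagged; a zero-valued optimum makes its relative
  perturbation degenerate (flagged, not skipped).
- **Network reduction**: for each retained-station count, random subsets are
  drawn (50 per size by default), held-out stations are predicted from the
  retained ones, and RMSE is aggregated to mean ± sd per size.
- **Support recovery**: backward elimination drops the single highest-p term
  while any non-intercept p exceeds the threshold. The default threshold for
  applied regression is 0.05. Support-recovery *experiments* use a stricter
  0.001: with three inactive predictors the per-dataset probability of a
  false inclusion is ≈ 1 − (1 − α)³, so α = 0.05 misses exact recovery in
  ~14% of datasets by design — that is the defined behavior of
  significance-based selection, not an estimation failure — while α = 0.001
  keeps it below 0.3%.

## 8. Known limitations

- **γ is weakly identified.** Sinuosity enters only through SI^γβ with SI
  confined to [1.05, 2.5]; the Fisher forecast routinely puts the relative
  sd of γ̂ above 100%. Calibrated γ values should not be interpreted
  physically on small networks.
- **α–β form a soft ridge.** Stream order grows downstream while travel
  time accumulates downstream, so their exponents are partially exchangeable.
  The ridge is non-quadratic: even on a design qualified by the (local)
  Fisher forecast, some noise realizations carry the global LOOCV optimum
  onto a parameter bound. Design qualification is therefore necessary, not
  sufficient, for precise recovery; recovery error varies across noise
  realizations more than the linearized forecast suggests.
- **Bootstrap intervals are heuristic.** Station resampling captures
  neighbor-configuration uncertainty and the residual add-on captures
  prediction noise, but the procedure has no formal coverage guarantee on
  tree-structured, heteroscedastic data; observed coverage on synthetic
  fields is conservative (at or above nominal).
- **Published coefficient tables are fixtures.** The zone/season linear
  models and the four second-degree polynomial models ship as read-only
  coefficient tables for evaluation only; refitting them requires the
  original basin dataset, which is not distributed with this package.
- The predictor is a convex combination: it cannot extrapolate above the
  maximum or below the minimum observed BOD₅, and it needs at least one
  flow-connected or same-basin neighbor with an observation to be defined.
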