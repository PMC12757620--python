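# hyrim

Hydro-geomorphic interpolation of river water quality along stream networks.

Biochemical oxygen demand (BOD₅) is routinely measured at a handful of
monitoring stations, yet management decisions are needed everywhere along a
river. Straight-line spatial interpolation ignores how rivers actually move
material: water follows the channel, influence decays with travel time, and
an upstream station tells you far more about a site than an equally distant
station on a different branch. `hyrim` predicts BOD₅ at unmonitored river
locations as a weighted average of the monitored stations, with weights built
from the network's hydro-geomorphic structure.

## The model

Monitoring stations sit on a dendritic river network (a tree of junctions and
flow-directed segments draining to one outlet). A neighbor station's
influence on a target location is

```
W = W_direction × Order^α / (T_t × SI^γ)^β
```

where `Order` is the neighbor's Strahler stream order, `T_t` the advective
travel time along the connecting channel path (Σ length / velocity), `SI` the
path's sinuosity index (channel length / straight-line distance, ≥ 1), and
`W_direction` a categorical flow-relation weight (upstream inflow counts
fully; downstream and disconnected branches are strongly discounted;
tributaries carry the calibratable coefficient δ). The prediction is the
W-weighted average of neighbor observations — always a convex combination,
so it can never leave the observed range.

The four exponents (α, β, γ, δ) are calibrated by minimizing leave-one-out
cross-validation RMSE with multi-start bounded quasi-Newton optimization.
Around the model sit the tools a monitoring programme needs: a 13-metric
evaluation suite (R², RMSE, …, PICP/MPIW/CWC, NLL/CRPS, Brier decomposition,
Taylor statistics), bootstrap prediction intervals with threshold-exceedance
probabilities, one-at-a-time sensitivity analysis, network-reduction
simulation, outlier screening for water-quality tables, and
backward-elimination / polynomial regression baselines with published
coefficient tables shipped as read-only fixtures.

## Worked example

Everything is testable without external data: seeded generators produce
dendritic networks and BOD₅ fields whose ground truth is known. Calibration
recovers the generating parameters from noisy observations
(`examples/02_calibrate_and_sensitivity.py`):

```text
network: 20 stations, 3 headwaters, 17 interior
generating truth: alpha=2.45, beta=0.512, gamma=0.225, delta=1.0
calibrated:       alpha=3.000, beta=0.976, gamma=0.046, delta=1.000
LOOCV RMSE at the optimum: 0.294 mg/L

OAT sensitivity (24 scenarios); RMSE increase vs optimum:
  beta  +50%: +52.75%
  alpha -50%: +41.07%
  beta  -50%: +25.89%
  delta -50%: +17.08%
  beta  +25%: +14.11%
```

The optimum reproduces the noise floor (RMSE 0.294 vs. injected noise sd
0.3) and every one-at-a-time perturbation makes it worse. The calibrated
exponents land on a soft α–β ridge rather than exactly on the truth — stream
order and travel time are topologically correlated on small networks, a
real identifiability limit discussed in `docs/methods.md`.

Bootstrap prediction intervals (`examples/03_bootstrap_uncertainty.py`):

```text
station_id  observed  median  lo95  hi95  p_exceed  n_replicates
      S000     12.19   12.09  7.03 13.06      0.90           500
      S001     12.01   12.08  7.06 13.15      0.89           500
      ...
empirical 95%-PI coverage over 20 stations: 1.00
```

The other examples cover single-prediction mechanics on a hand-built network
(`examples/01_…`) and the tabular pipeline — planted-outlier removal and
sparse-support recovery by backward elimination (`examples/04_…`):

```text
planted outliers: [5, 14, 22, 55, 67, 72, 89]
removed rows:     [5, 14, 22, 55, 67, 72, 89]
selected terms: ['T', 'DO']
coefficients: {'Intercept': 3.565, 'T': 0.511, 'DO': -0.772}
```

## Command line

The same pipeline is scriptable through a thin CLI; every subcommand writes
its artifacts plus a `manifest.json` (settings, config hash, versions) so any
output can be regenerated:

```bash
hyrim simulate --n-stations 20 --seed 0 --out run/
hyrim calibrate --stations run/stations.csv --network run/network.csv \
                --junctions run/junctions.csv --out run/cal/
hyrim bootstrap --stations run/stations.csv --network run/network.csv \
                --junctions run/junctions.csv --iterations 1000 --out run/boot/
```

Subcommands: `simulate`, `preprocess`, `calibrate`, `predict`, `evaluate`,
`bootstrap`, `sensitivity`, `reduce`, `regress`.

## Reproduction

`scripts/acceptance.py` runs the full pipeline end to end on seeded
synthetic data and reports the headline quantities (oracle agreement,
closure error, parameter-recovery error, OAT optimality margin, bootstrap
coverage, outlier recall, support-recovery rate, fixture evaluation) as
JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness in the package flows from explicit integer seeds; repeated
runs with the same seed are bit-identical. The methods, parameter semantics,
generator design and known limitations are documented in
[`docs/methods.md`](docs/methods.md).
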