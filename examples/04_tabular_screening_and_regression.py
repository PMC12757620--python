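"""Water-quality table preprocessing and regression baselines.

Plants gross outliers in a synthetic multivariate water-quality table,
removes them with the three-detector ensemble vote, then recovers a sparse
linear response by backward elimination and evaluates the suite of published
coefficient fixtures.
"""

import pandas as pd

from hyrim.synth import generate_wqv_table
from hyrim.tabular import (
    MLR_FIXTURES,
    TWO_DPR_FIXTURES,
    backward_eliminate,
    ensemble_outliers,
    predict_fixed,
)

# 100 rows, 7 planted outliers shifted 8 column-sd in every predictor
table, planted = generate_wqv_table(100, outlier_fraction=0.07, seed=0)
report = ensemble_outliers(table, seed=0)
print(f"planted outliers: {sorted(planted)}")
print(f"removed rows:     {sorted(report.removed_index)}")
print(f"rows surviving:   {len(report.surviving)} of {len(table)}")

# backward elimination on the clean table; true model is 4 + 0.5 T - 0.8 DO
clean = report.surviving
model = backward_eliminate(clean.drop(columns=["BOD5"]), clean["BOD5"],
                           alpha=0.001)
print("\nselected terms:", model.terms)
print("coefficients:", {k: round(v, 3) for k, v in model.coefficients.items()})
print(f"R2 = {model.r2:.3f}, eliminated: {model.eliminated}")

# published fixtures evaluate without refitting
zones = pd.DataFrame({"T": [18.0], "Tu": [30.0], "NO3": [2.5], "DO": [7.0],
                      "TS": [160.0], "FC": [25.0]})
print("\npublished-model predictions at one sample (mg/L):")
for name, m in MLR_FIXTURES.items():
    print(f"  MLR  {name:12s}: {predict_fixed(m, zones)[0]:8.2f}")
for name, m in TWO_DPR_FIXTURES.items():
    print(f"  2DPR {name:12s}: {predict_fixed(m, zones)[0]:8.2f}")
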