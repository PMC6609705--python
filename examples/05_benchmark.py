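"""Benchmark the comparison estimators on one synthetic cohort.

Evaluates SVR, SVR+RFE, RF, RF+RFE and the simplified CPM under the shared
5-fold protocol and prints a small table of R, P and MAE per method —
the same shape as a method-comparison results table.  CPM is skipped for
CON fusion because it requires matrix-shaped (R x R) input.
"""

import pandas as pd

import morphnet as mn

cohort, _ = mn.generate(mn.default_recovery_scenario(seed=0))
features = mn.cohort_features(cohort, "view2")
config = mn.PipelineConfig(
    rfe=mn.RFEConfig(scorer="rf", batch=0.5, scorer_forest=mn.RFConfig(n_trees=25)),
    n_features=50,
    forest=mn.RFConfig(),
    seed=0,
)

rows = []
for method in mn.BASELINE_METHODS:
    result = mn.run_baseline(method, features, cohort.ages, config)
    rows.append({"method": method, "R": round(result.pearson_r, 3),
                 "P": f"{result.p_value:.2e}", "MAE": round(result.mae, 2)})

print(pd.DataFrame(rows).to_string(index=False))
print("\nrf_rfe is the primary pipeline; rf omits feature selection; the "
      "simplified CPM sums significant positive/negative edges into two "
      "strength scores.")
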