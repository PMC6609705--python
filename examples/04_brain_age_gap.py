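"""The brain-age gap as a disorder biomarker.

Fits the healthy-baseline model on normal controls, predicts disordered
subjects' morphological age, and recovers the planted 5-year acceleration
as the group difference in mean signed gap.  Then classifies NC vs
disordered from network features augmented with the gap.
"""

import morphnet as mn

config = mn.PipelineConfig(
    rfe=mn.RFEConfig(scorer="rf", batch=0.2, scorer_forest=mn.RFConfig(n_trees=50)),
    n_features=15,
    forest=mn.RFConfig(),
    seed=0,
)

cohort, _ = mn.generate(mn.accelerated_scenario(acceleration_years=5.0, seed=0))
features = mn.cohort_features(cohort, "view2")
analysis = mn.gap_analysis(features, cohort.ages, cohort.groups, config)
print(f"mean signed gap, NC:         {analysis.mean_signed_gap('NC'):+.2f} years")
print(f"mean signed gap, disordered: {analysis.mean_signed_gap('DISORDERED'):+.2f} years")
print(f"group difference:            {analysis.group_difference:.2f} years "
      "(planted acceleration: 5.00)")
print("NC gaps are computed leave-fold-out, so they are honestly near zero; "
      "the disordered gap recovers most of the planted shift (random-forest "
      "regression slightly compresses the prediction slope).")

# Gap-augmented classification on the strongly separable scenario
sep_cohort, _ = mn.generate(mn.separable_scenario(seed=0))
sep_features = mn.cohort_features(sep_cohort, "view2")
clf = mn.classify_with_gap(sep_features, sep_cohort.ages, sep_cohort.groups, config)
print(f"\nseparable scenario classification: accuracy {clf.accuracy:.3f}, "
      f"sensitivity {clf.sensitivity:.3f}, specificity {clf.specificity:.3f}")
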